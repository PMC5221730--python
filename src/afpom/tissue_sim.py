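"""Monodomain tissue simulation on sheets, strips and spherical surfaces.

The tissue model is a homogeneous monodomain reaction–diffusion system:
every node carries one copy of the (possibly rescaled) AF cell model,
coupled through a discrete Laplacian with diffusion coefficient D
(cm²/ms).  Integration is Godunov operator splitting at a shared time
step: one Rush–Larsen/Euler reaction step followed by one explicit
diffusion step.

Meshes:

* ``sheet``  — regular 2D grid, 5-point Laplacian, zero-flux borders;
* ``strip``  — 1D cable (used for conduction-velocity measurements);
* ``sphere`` — icosphere (subdivided icosahedron) with a cotangent-weight
  Laplacian; closed surface, no boundaries.

Reentry can be started by cross-field (S1–S2) stimulation or by seeding
the limit-cycle phase of the cell around a chosen axis, which places a
fully formed spiral (pair of counter-rotating spirals on the sphere)
into the initial condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _crn
from .cell_model import (DEFAULT_STIM_AMPLITUDE, CellParams,
                         _get_tables, limit_cycle_states, resting_state)
from .errors import ConfigurationError, SimulationError, ValidationError

__all__ = ["Mesh", "BlockSpec", "VoltageMovie", "build_mesh",
           "initiate_reentry", "run_tissue", "measure_cv"]

#: default diffusion coefficient, cm^2/ms.  With the default dx = 0.05 cm
#: discretization this propagates a planar wave at ~33 cm/s in baseline AF
#: tissue, in the range reported for remodeled human atria.
DEFAULT_D = 1.0e-3
DEFAULT_DX = 0.05
DEFAULT_DT = 0.04


@dataclass
class Mesh:
    """Discretized surface carrying the tissue simulation.

    ``faces`` are the oriented elementary cycles (grid plaquettes or
    triangles) used for phase-singularity detection; ``laplacian`` is the
    CSR discrete Laplacian in cm^-2 whose rows sum to zero (zero-flux
    borders / closed surface).
    """

    points: np.ndarray           # (n, 3) cm
    faces: np.ndarray            # (n_faces, 3 or 4) node indices, oriented
    laplacian: sp.csr_matrix     # (n, n), cm^-2
    areas: np.ndarray            # (n,) cm^2
    topology: str                # sheet | strip | sphere | torus
    spacing: float               # characteristic inter-node distance, cm
    shape: tuple | None = None   # (ny, nx) for sheets/tori
    radius: float | None = None  # cm, spheres only
    period: float | None = None  # cm, tori only (periodic box length)
    face_centroids: np.ndarray | None = None  # (n_faces, 3), seam-aware

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    def __post_init__(self):
        rowsum = np.abs(self.laplacian.sum(axis=1)).max()
        if rowsum > 1e-6 / self.spacing ** 2:
            raise ValidationError(f"Laplacian rows do not sum to 0 ({rowsum})")
        if np.any(self.areas <= 0):
            raise ValidationError("node areas must be positive")


@dataclass(frozen=True)
class BlockSpec:
    """Conductance block: multiply ``name`` by ``multiplier`` from ``onset_ms``."""

    name: str
    multiplier: float
    onset_ms: float = 0.0

    def __post_init__(self):
        if self.name not in _crn.COND_NAMES:
            raise ConfigurationError(f"unknown conductance {self.name!r}")
        if not 0.0 <= self.multiplier <= 1.0:
            raise ValidationError("block multiplier must be in [0, 1]")


@dataclass
class VoltageMovie:
    """Node × time voltage with the mesh and run metadata.

    ``final_states`` is the complete 21-state field at the end of the
    run, so a follow-up (e.g. drug-block) simulation can continue from
    it.
    """

    frames: np.ndarray        # (n_frames, n_nodes) mV
    frame_ms: float
    mesh: Mesh
    log: dict = field(default_factory=dict)
    final_states: np.ndarray | None = None

    @property
    def duration_ms(self) -> float:
        return (self.frames.shape[0] - 1) * self.frame_ms

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames.shape[0]) * self.frame_ms

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("V", data=self.frames, compression="gzip")
            f.attrs["frame_ms"] = self.frame_ms
            g = f.create_group("mesh")
            g.create_dataset("points", data=self.mesh.points)
            g.create_dataset("faces", data=self.mesh.faces)
            if self.mesh.face_centroids is not None:
                g.create_dataset("face_centroids",
                                 data=self.mesh.face_centroids)
            g.attrs["topology"] = self.mesh.topology
            g.attrs["spacing"] = self.mesh.spacing
            if self.mesh.period is not None:
                g.attrs["period"] = self.mesh.period
            for key, value in self.log.items():
                f.attrs[f"log_{key}"] = str(value)
            if self.final_states is not None:
                f.create_dataset("final_states", data=self.final_states)

    @classmethod
    def from_hdf5(cls, path) -> "VoltageMovie":
        """Reload a movie with an analysis-grade mesh.

        The stored mesh carries the geometry the rotor analysis needs
        (points, faces, centroids, topology, spacing, period); the
        Laplacian is not persisted, so the returned mesh cannot be
        simulated on — rebuild it with :func:`build_mesh` for that.
        """
        import h5py

        with h5py.File(path, "r") as f:
            g = f["mesh"]
            points = g["points"][:]
            n = points.shape[0]
            mesh = Mesh(points, g["faces"][:],
                        sp.csr_matrix((n, n)), np.full(n, 1.0),
                        g.attrs["topology"], float(g.attrs["spacing"]),
                        period=(float(g.attrs["period"])
                                if "period" in g.attrs else None),
                        face_centroids=(g["face_centroids"][:]
                                        if "face_centroids" in g else None))
            frames = f["V"][:]
            final = (f["final_states"][:] if "final_states" in f else None)
            log = {k[4:]: f.attrs[k] for k in f.attrs if k.startswith("log_")}
            return cls(frames, float(f.attrs["frame_ms"]), mesh, log=log,
                       final_states=final)


def _sheet_laplacian(ny: int, nx: int, dx: float) -> sp.csr_matrix:
    """5-point Laplacian with mirrored (zero-flux) borders."""
    rows, cols, vals = [], [], []
    for i in range(ny):
        for j in range(nx):
            k = i * nx + j
            deg = 0
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if 0 <= a < ny and 0 <= b < nx:
                    rows.append(k)
                    cols.append(a * nx + b)
                    vals.append(1.0)
                    deg += 1
            rows.append(k)
            cols.append(k)
            vals.append(-float(deg))
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(ny * nx, ny * nx))
    return (lap / dx ** 2).tocsr()


def _cotangent_laplacian(points: np.ndarray, faces: np.ndarray) -> tuple:
    """Cotangent-weight Laplacian and barycentric vertex areas."""
    n = points.shape[0]
    areas = np.zeros(n)
    w = {}
    for tri in faces:
        p = points[tri]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        for v in tri:
            areas[v] += area / 3.0
        for c in range(3):
            i, j, k = tri[c], tri[(c + 1) % 3], tri[(c + 2) % 3]
            u1, u2 = points[i] - points[k], points[j] - points[k]
            cot = float(np.dot(u1, u2) / max(np.linalg.norm(np.cross(u1, u2)), 1e-300))
            key = (min(i, j), max(i, j))
            w[key] = w.get(key, 0.0) + 0.5 * cot
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for (i, j), wij in w.items():
        wi, wj = wij / areas[i], wij / areas[j]
        rows += [i, j]
        cols += [j, i]
        vals += [wi, wj]
        diag[i] -= wi
        diag[j] -= wj
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return lap.tocsr(), areas


def build_mesh(kind: str, size: float = 3.0, dx: float = DEFAULT_DX,
               radius: float = 2.5, subdivisions: int = 4) -> Mesh:
    """Construct a simulation mesh.

    ``sheet``: square of side ``size`` cm at node spacing ``dx``
    (zero-flux borders).  ``torus``: doubly periodic square of period
    ``size`` — the cheap closed surface; rotors live on it in
    counter-rotating pairs exactly as on the sphere.  ``strip``: 1D
    cable of length ``size``.  ``sphere``: icosphere of the given
    ``radius`` (cm) and subdivision level.  A warning is emitted when
    the spacing exceeds 0.05 cm, the resolution needed at the default
    conduction settings.
    """
    if kind == "torus":
        if size <= 0 or dx <= 0 or size < 4 * dx:
            raise ValidationError("degenerate torus size")
        n = int(round(size / dx))
        period = n * dx
        xs = np.arange(n) * dx
        gx, gy = np.meshgrid(xs, xs)
        points = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
        rows, cols, vals = [], [], []
        for i in range(n):
            for j in range(n):
                k = i * n + j
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rows.append(k)
                    cols.append(((i + di) % n) * n + (j + dj) % n)
                    vals.append(1.0)
                rows.append(k)
                cols.append(k)
                vals.append(-4.0)
        lap = (sp.csr_matrix((vals, (rows, cols)), shape=(n * n, n * n))
               / dx ** 2).tocsr()
        quads = []
        for i in range(n):
            for j in range(n):
                k = i * n + j
                right = i * n + (j + 1) % n
                down = ((i + 1) % n) * n + j
                diag = ((i + 1) % n) * n + (j + 1) % n
                quads.append((k, right, diag, down))
        quads = np.asarray(quads)
        # seam-aware centroids: average minimum-image offsets from the
        # anchor vertex, then wrap back into the box
        anchor = points[quads[:, 0]]
        offs = points[quads] - anchor[:, None, :]
        offs[..., :2] = (offs[..., :2] + period / 2) % period - period / 2
        centroids = anchor + offs.mean(axis=1)
        centroids[:, :2] %= period
        mesh = Mesh(points, quads, lap, np.full(n * n, dx ** 2), "torus", dx,
                    shape=(n, n), period=period, face_centroids=centroids)
    elif kind == "sheet":
        if size <= 0 or dx <= 0 or size < 2 * dx:
            raise ValidationError("degenerate sheet size")
        nx = int(round(size / dx)) + 1
        xs = np.arange(nx) * dx
        gx, gy = np.meshgrid(xs, xs)
        points = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(nx * nx)])
        lap = _sheet_laplacian(nx, nx, dx)
        # oriented grid plaquettes (counterclockwise in the x-y plane)
        quads = []
        for i in range(nx - 1):
            for j in range(nx - 1):
                k = i * nx + j
                quads.append((k, k + 1, k + nx + 1, k + nx))
        quads = np.asarray(quads)
        mesh = Mesh(points, quads, lap,
                    np.full(nx * nx, dx ** 2), "sheet", dx, shape=(nx, nx),
                    face_centroids=points[quads].mean(axis=1))
    elif kind == "strip":
        if size <= 0 or dx <= 0 or size < 2 * dx:
            raise ValidationError("degenerate strip size")
        n = int(round(size / dx)) + 1
        points = np.column_stack([np.arange(n) * dx, np.zeros(n), np.zeros(n)])
        main = -2.0 * np.ones(n)
        main[0] = main[-1] = -1.0
        lap = (sp.diags([np.ones(n - 1), main, np.ones(n - 1)], [-1, 0, 1])
               / dx ** 2).tocsr()
        mesh = Mesh(points, np.empty((0, 3), dtype=int), lap,
                    np.full(n, dx), "strip", dx)
    elif kind == "sphere":
        import trimesh

        if radius <= 0:
            raise ValidationError("degenerate sphere radius")
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        points = np.asarray(ico.vertices, dtype=float)
        faces = np.asarray(ico.faces, dtype=int)
        if points.shape[0] - ico.edges_unique.shape[0] + faces.shape[0] != 2:
            raise ValidationError("icosphere is not a closed surface")
        lap, areas = _cotangent_laplacian(points, faces)
        spacing = float(np.mean(np.linalg.norm(
            points[ico.edges_unique[:, 0]] - points[ico.edges_unique[:, 1]],
            axis=1)))
        mesh = Mesh(points, faces, lap, areas, "sphere", spacing, radius=radius,
                    face_centroids=points[faces].mean(axis=1))
    else:
        raise ConfigurationError(f"unknown mesh kind {kind!r}")
    if mesh.spacing > 0.05 + 1e-12:
        warnings.warn(
            f"inter-node spacing {mesh.spacing:.3f} cm exceeds 0.05 cm; "
            "too coarse for the default conduction settings", stacklevel=2)
    return mesh


def export_mesh(mesh: Mesh, path) -> None:
    """Write the mesh surface to PLY/OFF/etc. for visualization."""
    import trimesh

    if mesh.faces.shape[1] == 4:
        tris = np.vstack([mesh.faces[:, [0, 1, 2]], mesh.faces[:, [0, 2, 3]]])
    else:
        tris = mesh.faces
    trimesh.Trimesh(mesh.points, tris, process=False).export(path)


def _check_cfl(mesh: Mesh, dcoef: float, dt: float) -> None:
    # explicit diffusion stability: dt * D * |diag(L)| <= 1 with margin
    max_diag = float(np.abs(mesh.laplacian.diagonal()).max())
    if dt * dcoef * max_diag > 0.5:
        raise ValidationError(
            f"unstable discretization: dt*D*|L_ii| = {dt * dcoef * max_diag:.2f} "
            "> 0.5; reduce dt or D, or coarsen the mesh")


def run_tissue(
    mesh: Mesh,
    params: CellParams,
    init_states: np.ndarray | None = None,
    duration_ms: float = 2000.0,
    dt: float = DEFAULT_DT,
    dcoef: float = DEFAULT_D,
    block: BlockSpec | None = None,
    frame_ms: float = 1.0,
    stim: tuple | None = None,
) -> VoltageMovie:
    """Integrate the monodomain model and record a voltage movie.

    ``init_states`` is an (n_nodes, 21) state field (default: uniform
    rest).  ``stim`` is an optional single episode
    ``(node_mask, amplitude, start_ms, end_ms)``.  With a ``block``, the
    target maximal conductance is multiplied from the block onset
    onward; frames before the onset are identical to an unblocked run.
    Deterministic for identical inputs.
    """
    _check_cfl(mesh, dcoef, dt)
    n = mesh.n_nodes
    if init_states is None:
        states = np.tile(resting_state(), (n, 1))
    else:
        states = np.array(init_states, dtype=float)
        if states.shape != (n, _crn.N_STATES):
            raise ValidationError(
                f"init_states must have shape {(n, _crn.N_STATES)}")
    cond0 = params.cond
    log: dict = {"duration_ms": duration_ms, "dt": dt, "D": dcoef}
    if block is not None:
        cond1 = cond0.copy()
        cond1[_crn.COND_NAMES.index(block.name)] *= block.multiplier
        switch_step = int(round(block.onset_ms / dt))
        log["block"] = (f"{block.name}x{block.multiplier:g}"
                        f"@{block.onset_ms:g}ms")
    else:
        cond1 = cond0
        switch_step = np.iinfo(np.int64).max
    if stim is None:
        stim_mask = np.zeros(n, dtype=bool)
        stim_amp, s0, s1 = 0.0, np.iinfo(np.int64).max, np.iinfo(np.int64).max
    else:
        mask, stim_amp, start_ms, end_ms = stim
        stim_mask = np.asarray(mask, dtype=bool)
        s0, s1 = int(round(start_ms / dt)), int(round(end_ms / dt))

    frame_every = max(1, int(round(frame_ms / dt)))
    n_steps = int(round(duration_ms / dt))
    n_steps -= n_steps % frame_every
    frames = np.empty((n_steps // frame_every + 1, n), dtype=np.float64)
    lap = mesh.laplacian
    fail = _crn.run_tissue(states, dt, n_steps, cond0, cond1, switch_step,
                           _get_tables(dt), dcoef, lap.indptr, lap.indices,
                           lap.data, stim_amp, stim_mask, s0, s1,
                           frame_every, frames)
    if fail >= 0:
        bad = int(np.flatnonzero(~np.isfinite(states[:, 0]))[0])
        raise SimulationError(
            f"tissue solver diverged at t = {fail * dt:.2f} ms, node {bad}")
    return VoltageMovie(frames, frame_every * dt, mesh,
                        log=log, final_states=states)


def initiate_reentry(
    mesh: Mesh,
    params: CellParams,
    method: str = "phase_seed",
    cycle_ms: float = 250.0,
    dt: float = DEFAULT_DT,
    dcoef: float = DEFAULT_D,
    chirality: int = +1,
) -> np.ndarray:
    """Initial state field expected to spawn at least one rotor.

    ``phase_seed`` wraps one paced limit cycle of the cell around the
    mesh center (sheet) or around the z axis (sphere, giving a
    counter-rotating pair, net topological charge 0).  ``cross_field``
    runs an S1 planar wave from the x-min edge and fires an S2 over the
    lower half-domain as soon as the repolarization tail clears the
    domain center.
    """
    if method == "phase_seed":
        cycle = limit_cycle_states(params, cycle_ms=cycle_ms)
        pts = mesh.points
        if mesh.topology == "sphere":
            theta = np.arctan2(pts[:, 1], pts[:, 0]) % (2 * np.pi)
        elif mesh.topology == "torus":
            # vortex-antivortex pair: the angle difference is continuous
            # across the periodic seams and carries net winding zero
            half = mesh.period / 2
            th_a = np.arctan2(chirality * (pts[:, 1] - half),
                              pts[:, 0] - half / 2)
            th_b = np.arctan2(chirality * (pts[:, 1] - half),
                              pts[:, 0] - 3 * half / 2)
            theta = np.angle(np.exp(1j * (th_a - th_b))) % (2 * np.pi)
        else:
            center = pts.mean(axis=0)
            theta = np.arctan2(chirality * (pts[:, 1] - center[1]),
                               pts[:, 0] - center[0]) % (2 * np.pi)
        idx = (theta / (2 * np.pi) * cycle.shape[0]).astype(int)
        return cycle[np.clip(idx, 0, cycle.shape[0] - 1)].copy()
    if method == "cross_field":
        return _cross_field_states(mesh, params, dt, dcoef)
    raise ConfigurationError(f"unknown initiation method {method!r}")


def _cross_field_states(mesh: Mesh, params: CellParams, dt: float,
                        dcoef: float) -> np.ndarray:
    if mesh.topology != "sheet":
        raise ConfigurationError("cross-field initiation needs a sheet mesh")
    pts = mesh.points
    xmax, ymax = pts[:, 0].max(), pts[:, 1].max()
    s1_mask = pts[:, 0] <= 2.01 * mesh.spacing
    center = int(np.argmin((pts[:, 0] - xmax / 2) ** 2
                           + (pts[:, 1] - ymax / 2) ** 2))
    states = np.tile(resting_state(), (mesh.n_nodes, 1))
    movie = run_tissue(mesh, params, states, duration_ms=20.0, dt=dt,
                       dcoef=dcoef,
                       stim=(s1_mask, DEFAULT_STIM_AMPLITUDE, 0.0, 3.0))
    states = movie.final_states
    excited = False
    for _ in range(60):  # poll in 10-ms chunks, up to 600 ms
        movie = run_tissue(mesh, params, states, duration_ms=10.0, dt=dt,
                           dcoef=dcoef)
        states = movie.final_states
        v_center = states[center, 0]
        if v_center > -20.0:
            excited = True
        if excited and v_center < -65.0:
            break
    else:
        raise SimulationError("S1 wave never cleared the domain center")
    s2_mask = pts[:, 1] <= ymax / 2
    movie = run_tissue(mesh, params, states, duration_ms=5.0, dt=dt,
                       dcoef=dcoef,
                       stim=(s2_mask, DEFAULT_STIM_AMPLITUDE, 0.0, 3.0))
    return movie.final_states


def measure_cv(
    params: CellParams | None = None,
    dx: float = 0.025,
    dcoef: float = DEFAULT_D,
    dt: float | None = None,
    length: float = 2.0,
    gna_scale: float = 1.0,
) -> float:
    """Planar conduction velocity (cm/s) on a 1D strip.

    Stimulates one end and times the activation (−40 mV crossing)
    between the 1/4 and 3/4 points.  Used by the diffusion-tuning and
    numerics-validation workflows.
    """
    from .cell_model import scale_conductances

    params = params or CellParams.af_baseline()
    if gna_scale != 1.0:
        params = scale_conductances(params, {"gNa": gna_scale})
    if dt is None:
        dt = min(DEFAULT_DT, 0.4 * dx ** 2 / (2.0 * dcoef))
    mesh = build_mesh("strip", size=length, dx=dx)
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    mask[:3] = True
    frame_ms = max(dt, 0.25)
    movie = run_tissue(mesh, params, None, duration_ms=80.0, dt=dt,
                       dcoef=dcoef, frame_ms=frame_ms,
                       stim=(mask, 2 * DEFAULT_STIM_AMPLITUDE, 0.0, 2.0))
    n = mesh.n_nodes
    t_act = []
    for node in (n // 4, 3 * n // 4):
        v = movie.frames[:, node].astype(float)
        above = np.flatnonzero(v > -40.0)
        if above.size == 0 or above[0] == 0:
            raise SimulationError("wave failed to reach the measurement points")
        k = above[0]
        # sub-frame activation time by linear interpolation of the crossing
        frac = (-40.0 - v[k - 1]) / (v[k] - v[k - 1])
        t_act.append((k - 1 + frac) * movie.frame_ms)
    dist_cm = (3 * n // 4 - n // 4) * dx
    if t_act[1] <= t_act[0]:
        raise SimulationError("no forward propagation measured")
    return dist_cm / (t_act[1] - t_act[0]) * 1000.0
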