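"""Phase mapping, rotor-core detection/tracking and reentry biomarkers.

From a tissue voltage movie this module derives:

* a phase movie (analytic-signal phase of the mean-subtracted voltage,
  or a time-delay embedding);
* phase singularities (PS): mesh faces whose oriented boundary winds the
  phase by ±2π, the instantaneous rotor cores;
* core trajectories (greedy nearest-neighbor tracking with a same-charge
  constraint and a maximum-jump gate);
* rotor meandering (RM): convex-hull area of the dominant core
  trajectory, in cm²;
* dominant frequency (DF): per-node frequency of the highest
  power-spectral-density peak in 1–20 Hz, aggregated as the modal value;
* termination detection: the movie terminated once no PS exists and no
  node exceeds −40 mV for a contiguous 300 ms, tagged "core collision"
  when the last two opposite-charge cores died within the tracking gate
  of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import ConvexHull, QhullError

from .errors import ValidationError
from .tissue_sim import Mesh, VoltageMovie

__all__ = ["PhaseMovie", "PhaseSingularity", "CoreTrajectory",
           "ReentryBiomarkers", "compute_phase", "detect_singularities",
           "singularities_by_frame", "track_cores", "meandering_area",
           "dominant_frequency", "detect_termination", "reentry_biomarkers"]

ACTIVATION_THRESHOLD_MV = -40.0
QUIET_MS = 300.0
#: tracking gate, in units of inter-node spacing
GATE_SPACINGS = 4.0


@dataclass
class PhaseMovie:
    """Per-node activation phase in (−π, π]; flat nodes are flagged invalid."""

    phase: np.ndarray      # (n_frames, n_nodes)
    mesh: Mesh
    frame_ms: float
    valid: np.ndarray      # (n_nodes,) bool


@dataclass(frozen=True)
class PhaseSingularity:
    time_ms: float
    position: tuple        # (x, y, z) cm
    charge: int            # +1 or -1
    face: int


@dataclass
class CoreTrajectory:
    """Time-ordered positions of one tracked rotor core (filament)."""

    charge: int
    times: list = field(default_factory=list)       # ms
    positions: list = field(default_factory=list)   # (3,) arrays

    @property
    def birth_ms(self) -> float:
        return self.times[0]

    @property
    def death_ms(self) -> float:
        return self.times[-1]

    @property
    def lifetime_ms(self) -> float:
        return self.times[-1] - self.times[0]


@dataclass(frozen=True)
class ReentryBiomarkers:
    """Summary of one reentry simulation."""

    df_hz: float
    rm_cm2: float
    sustained: bool
    termination_ms: float | None
    mechanism: str          # "" | "core collision" | "boundary" | "unknown"


def compute_phase(movie: VoltageMovie, method: str = "hilbert",
                  delay_ms: float = 10.0) -> PhaseMovie:
    """Per-node phase of the activation cycle.

    ``hilbert``: angle of the analytic signal of the mean-subtracted
    voltage (needs a couple of activation cycles to be meaningful).
    ``delay``: time-delay embedding, angle of
    (V(t−τ) − V̄, V(t) − V̄).  Nodes with (numerically) constant voltage
    have no defined phase and are flagged invalid.
    """
    v = movie.frames.astype(np.float64)
    centered = v - v.mean(axis=0)
    valid = v.std(axis=0) > 1e-6
    if method == "hilbert":
        phase = np.angle(hilbert(centered, axis=0))
    elif method == "delay":
        lag = max(1, int(round(delay_ms / movie.frame_ms)))
        delayed = np.vstack([np.repeat(centered[:1], lag, axis=0),
                             centered[:-lag]])
        phase = np.arctan2(delayed, centered)
    else:
        raise ValidationError(f"unknown phase method {method!r}")
    phase[:, ~valid] = 0.0
    return PhaseMovie(phase, movie.mesh, movie.frame_ms, valid)


def _face_winding(phase_frame: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Winding number of each oriented face boundary (in turns)."""
    total = np.zeros(faces.shape[0])
    k = faces.shape[1]
    for e in range(k):
        d = phase_frame[faces[:, (e + 1) % k]] - phase_frame[faces[:, e]]
        total += (d + np.pi) % (2 * np.pi) - np.pi
    return total / (2 * np.pi)


def detect_singularities(phase_frame: np.ndarray, mesh: Mesh,
                         time_ms: float = 0.0) -> list:
    """Phase singularities of one frame.

    A PS is reported for every face whose boundary phase-difference sum
    (each difference wrapped to (−π, π]) equals ±2π; its position is the
    face centroid.
    """
    w = np.round(_face_winding(phase_frame, mesh.faces)).astype(int)
    centroids = (mesh.face_centroids if mesh.face_centroids is not None
                 else mesh.points[mesh.faces].mean(axis=1))
    out = []
    for f in np.flatnonzero(w != 0):
        out.append(PhaseSingularity(time_ms, tuple(centroids[f]),
                                    int(np.sign(w[f])), int(f)))
    return out


def singularities_by_frame(pm: PhaseMovie) -> list:
    """PS lists for every frame (vectorized over the movie)."""
    faces = pm.mesh.faces
    total = np.zeros((pm.phase.shape[0], faces.shape[0]))
    k = faces.shape[1]
    for e in range(k):
        d = pm.phase[:, faces[:, (e + 1) % k]] - pm.phase[:, faces[:, e]]
        total += (d + np.pi) % (2 * np.pi) - np.pi
    w = np.round(total / (2 * np.pi)).astype(np.int8)
    centroids = (pm.mesh.face_centroids if pm.mesh.face_centroids is not None
                 else pm.mesh.points[faces].mean(axis=1))
    out = []
    for t in range(w.shape[0]):
        time_ms = t * pm.frame_ms
        out.append([PhaseSingularity(time_ms, tuple(centroids[f]),
                                     int(np.sign(w[t, f])), int(f))
                    for f in np.flatnonzero(w[t] != 0)])
    return out


def _min_image(disp: np.ndarray, period: float | None) -> np.ndarray:
    """Minimum-image displacement on a doubly periodic (torus) domain."""
    if period is not None:
        disp = disp.copy()
        disp[..., :2] = (disp[..., :2] + period / 2) % period - period / 2
    return disp


def track_cores(ps_by_frame: list, frame_ms: float,
                gate_cm: float, period: float | None = None) -> list:
    """Associate per-frame singularities into core trajectories.

    Greedy nearest-neighbor linking: in each frame every surviving
    trajectory claims the closest unclaimed PS of its own charge within
    ``gate_cm``; unmatched PS start new trajectories, unmatched
    trajectories end.  On periodic domains (``period`` set) distances
    use the minimum-image convention and stored positions are unwrapped
    along each trajectory, so meander hulls are seam-free.
    """
    active: list[CoreTrajectory] = []
    done: list[CoreTrajectory] = []
    for t, ps_list in enumerate(ps_by_frame):
        time_ms = ps_list[0].time_ms if ps_list else t * frame_ms
        pos = np.array([p.position for p in ps_list]).reshape(-1, 3)
        charges = np.array([p.charge for p in ps_list], dtype=int)
        claimed = np.zeros(len(ps_list), dtype=bool)
        # candidate links sorted by distance
        links = []
        for ai, traj in enumerate(active):
            head = traj.positions[-1]
            for pi in range(len(ps_list)):
                if charges[pi] != traj.charge:
                    continue
                disp = _min_image(pos[pi] - head, period)
                dist = float(np.linalg.norm(disp))
                if dist <= gate_cm:
                    links.append((dist, ai, pi))
        links.sort()
        matched_traj = set()
        for dist, ai, pi in links:
            if ai in matched_traj or claimed[pi]:
                continue
            matched_traj.add(ai)
            claimed[pi] = True
            head = active[ai].positions[-1]
            active[ai].times.append(time_ms)
            active[ai].positions.append(head + _min_image(pos[pi] - head,
                                                          period))
        survivors = []
        for ai, traj in enumerate(active):
            (survivors if ai in matched_traj else done).append(traj)
        active = survivors
        for pi in range(len(ps_list)):
            if not claimed[pi]:
                active.append(CoreTrajectory(int(charges[pi]), [time_ms],
                                             [pos[pi]]))
    done.extend(active)
    done.sort(key=lambda tr: tr.birth_ms)
    return done


def _tangent_coords(positions: np.ndarray, mesh: Mesh | None) -> np.ndarray:
    """2D coordinates of trajectory points (tangent plane on spheres)."""
    if mesh is not None and mesh.topology == "sphere":
        normal = positions.mean(axis=0)
        nrm = np.linalg.norm(normal)
        if nrm < 1e-12:
            normal = np.array([0.0, 0.0, 1.0])
        else:
            normal = normal / nrm
        helper = np.array([1.0, 0.0, 0.0])
        if abs(normal @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(normal, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        return np.column_stack([positions @ e1, positions @ e2])
    return positions[:, :2]


def meandering_area(traj: CoreTrajectory, mesh: Mesh | None = None) -> float:
    """Convex-hull area (cm²) swept by a core trajectory.

    Spherical trajectories are projected onto the tangent plane at their
    mean direction first.  Degenerate trajectories (fewer than three
    distinct, non-collinear points) have zero area.
    """
    pos = np.asarray(traj.positions).reshape(-1, 3)
    if pos.shape[0] < 3:
        return 0.0
    xy = _tangent_coords(pos, mesh)
    try:
        return float(ConvexHull(xy).volume)  # "volume" is area in 2D
    except QhullError:
        return 0.0


def dominant_frequency(
    movie: VoltageMovie,
    band: tuple = (1.0, 20.0),
    skip_ms: float = 0.0,
    aggregate: str = "mode",
) -> tuple:
    """Per-node DF map (Hz) and its scalar aggregate.

    DF is the frequency of the highest PSD peak within ``band``; the PSD
    is a zero-padded periodogram of the Hann-windowed, mean-subtracted
    voltage (padding interpolates the peak past the raw 1/T spacing).
    The scalar is the modal per-node DF (or max, configurable).  Flat
    movies return NaN.
    """
    start = int(round(skip_ms / movie.frame_ms))
    v = movie.frames[start:].astype(np.float64)
    n = v.shape[0]
    if n * movie.frame_ms < 500.0:
        raise ValidationError("movie too short for spectral analysis")
    fs = 1000.0 / movie.frame_ms
    nfft = int(2 ** math.ceil(math.log2(4 * n)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    window = np.hanning(n)
    df_map = np.full(v.shape[1], np.nan)
    for lo in range(0, v.shape[1], 512):
        chunk = v[:, lo:lo + 512]
        centered = chunk - chunk.mean(axis=0)
        flat = centered.std(axis=0) <= 1e-6
        spec = np.abs(np.fft.rfft(centered * window[:, None], n=nfft,
                                  axis=0)) ** 2
        peak = freqs[sel][np.argmax(spec[sel], axis=0)]
        peak[flat] = np.nan
        df_map[lo:lo + 512] = peak
    good = df_map[np.isfinite(df_map)]
    if good.size == 0:
        return df_map, float("nan")
    if aggregate == "mode":
        vals, counts = np.unique(np.round(good, 2), return_counts=True)
        scalar = float(vals[np.argmax(counts)])
    elif aggregate == "max":
        scalar = float(good.max())
    else:
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    return df_map, scalar


def detect_termination(
    movie: VoltageMovie,
    ps_by_frame: list | None = None,
    threshold_mv: float = ACTIVATION_THRESHOLD_MV,
    quiet_ms: float = QUIET_MS,
    gate_cm: float | None = None,
) -> tuple:
    """(sustained, termination time, mechanism tag).

    The run terminated at the start of the first window of at least
    ``quiet_ms`` during which no node exceeds ``threshold_mv`` and no
    phase singularity exists.  The mechanism is "core collision" when
    the last two opposite-charge core trajectories died within the
    tracking gate of each other, "boundary" when the last core died
    within two node spacings of a sheet border, else "unknown".
    """
    active = movie.frames.max(axis=1) > threshold_mv
    if ps_by_frame is not None:
        has_ps = np.array([len(p) > 0 for p in ps_by_frame])
        m = min(active.size, has_ps.size)
        active = active[:m] | has_ps[:m]
    quiet_frames = int(round(quiet_ms / movie.frame_ms))
    inactive = ~active
    run = 0
    t_term = None
    for i, q in enumerate(inactive):
        run = run + 1 if q else 0
        if run >= quiet_frames:
            t_term = (i - run + 1) * movie.frame_ms
            break
    if t_term is None:
        return True, None, ""
    mechanism = "unknown"
    if ps_by_frame is not None and gate_cm is not None:
        period = movie.mesh.period
        trajs = track_cores(ps_by_frame, movie.frame_ms, gate_cm,
                            period=period)
        died = [tr for tr in trajs if tr.death_ms <= t_term + movie.frame_ms]
        died.sort(key=lambda tr: tr.death_ms)
        if len(died) >= 2:
            a, b = died[-1], died[-2]
            close_in_time = abs(a.death_ms - b.death_ms) <= 5 * movie.frame_ms
            close_in_space = (np.linalg.norm(_min_image(
                np.asarray(a.positions[-1]) - np.asarray(b.positions[-1]),
                period)) <= gate_cm)
            if a.charge == -b.charge and close_in_time and close_in_space:
                mechanism = "core collision"
        if mechanism == "unknown" and died and movie.mesh.topology == "sheet":
            pts = movie.mesh.points
            p = np.asarray(died[-1].positions[-1])
            margin = 2.0 * movie.mesh.spacing
            if (p[0] < pts[:, 0].min() + margin or p[0] > pts[:, 0].max() - margin
                    or p[1] < pts[:, 1].min() + margin
                    or p[1] > pts[:, 1].max() - margin):
                mechanism = "boundary"
    return False, float(t_term), mechanism


def reentry_biomarkers(
    movie: VoltageMovie,
    skip_ms: float = 250.0,
    min_track_ms: float = 100.0,
) -> ReentryBiomarkers:
    """DF, RM and sustained/termination summary of one simulation.

    The first ``skip_ms`` are excluded from DF/RM measurement (initiation
    transient).  RM is the maximum convex-hull area over core
    trajectories living at least ``min_track_ms`` (falling back to the
    longest-lived trajectory when none persists that long).

    Phase is computed over the electrically active part of the movie
    only: after an early termination the analytic signal of the long
    quiescent tail is meaningless and would corrupt singularity
    detection (and hence the mechanism tag).
    """
    gate = GATE_SPACINGS * movie.mesh.spacing
    # first pass: voltage-threshold termination time
    sustained0, t_term0, _ = detect_termination(movie)
    act_ms = (movie.duration_ms if t_term0 is None
              else min(movie.duration_ms, t_term0 + QUIET_MS))
    n_act = int(round(act_ms / movie.frame_ms)) + 1
    active = VoltageMovie(movie.frames[:n_act], movie.frame_ms, movie.mesh)
    pm = compute_phase(active)
    ps = singularities_by_frame(pm)
    sustained, t_term, mechanism = detect_termination(active, ps,
                                                      gate_cm=gate)
    if sustained0 and not sustained:
        # PS-free but still electrically active: keep the voltage verdict
        sustained, t_term, mechanism = sustained0, t_term0, ""
    elif not sustained0:
        sustained = False
        t_term = t_term0 if t_term is None else min(t_term, t_term0)

    end_ms = act_ms if t_term is None else t_term
    lo = int(round(skip_ms / movie.frame_ms))
    hi = int(round(end_ms / movie.frame_ms))
    if hi - lo < 2:
        return ReentryBiomarkers(float("nan"), 0.0, sustained, t_term,
                                 mechanism)
    trajs = track_cores(ps[lo:hi], movie.frame_ms, gate,
                        period=movie.mesh.period)
    if trajs:
        long_lived = [tr for tr in trajs if tr.lifetime_ms >= min_track_ms]
        pool = long_lived or [max(trajs, key=lambda tr: tr.lifetime_ms)]
        rm = max(meandering_area(tr, movie.mesh) for tr in pool)
    else:
        rm = 0.0
    window = VoltageMovie(movie.frames[lo:hi], movie.frame_ms, movie.mesh)
    if (hi - lo) * movie.frame_ms >= 500.0:
        _, df = dominant_frequency(window)
    else:
        df = float("nan")
    return ReentryBiomarkers(df, rm, sustained, t_term, mechanism)


def render_aitoff_phase(pm: PhaseMovie, frame: int, path) -> None:
    """Save an Aitoff-projection phase map of one spherical frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pm.mesh.topology != "sphere":
        raise ValidationError("Aitoff projection needs a sphere mesh")
    pts = pm.mesh.points
    r = np.linalg.norm(pts, axis=1)
    lon = np.arctan2(pts[:, 1], pts[:, 0])
    lat = np.arcsin(np.clip(pts[:, 2] / r, -1.0, 1.0))
    fig = plt.figure(figsize=(6, 3.2))
    ax = fig.add_subplot(111, projection="aitoff")
    sc = ax.scatter(lon, lat, c=pm.phase[frame], s=4, cmap="twilight",
                    vmin=-np.pi, vmax=np.pi)
    for ps in detect_singularities(pm.phase[frame], pm.mesh):
        p = np.asarray(ps.position)
        ax.plot(np.arctan2(p[1], p[0]),
                np.arcsin(np.clip(p[2] / np.linalg.norm(p), -1, 1)),
                "o", mfc="none", mec="k", ms=10)
    ax.grid(True, alpha=0.3)
    fig.colorbar(sc, ax=ax, label="phase (rad)", shrink=0.7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
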