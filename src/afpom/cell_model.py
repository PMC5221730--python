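"""Chronic-AF remodeled human atrial cell model with scalable conductances.

The membrane kinetics are the Courtemanche–Ramirez–Nattel (1998) human
atrial model with standard chronic-AF electrical remodeling applied
(Ito −50%, ICaL −70%, IK1 +100%); see :mod:`afpom._crn` for the
equations.  On top of this baseline, eleven maximal conductances/fluxes
can be rescaled multiplicatively to build a population of
electrophysiologically distinct virtual cells: each scale factor ranges
over [0, 3], i.e. −100% to +200% of its remodeled nominal value.

Integration uses Rush–Larsen updates for gating variables and forward
Euler for voltage and concentrations (default dt = 0.02 ms), which is
robust for the stiff INa gates and exactly reproducible run-to-run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import _crn
from .errors import ConfigurationError, SimulationError, ValidationError

__all__ = [
    "SAMPLED_CONDUCTANCES",
    "CellParams",
    "PacingProtocol",
    "VoltageTrace",
    "scale_conductances",
    "derivatives",
    "simulate_cell",
    "diastolic_threshold",
    "DEFAULT_STIM_AMPLITUDE",
]

#: The eleven conductances/fluxes sampled when building a population:
#: fast sodium, L-type calcium, transient outward, ultrarapid (sustained)
#: outward, rapid and slow delayed rectifiers, inward rectifier, Na/K pump,
#: Na/Ca exchanger, sarcolemmal Ca pump, and SERCA uptake maxima.
#: Membership is configurable wherever a ``names`` argument is accepted.
SAMPLED_CONDUCTANCES: tuple[str, ...] = (
    "gNa", "gCaL", "gto", "gKur", "gKr", "gKs", "gK1",
    "gNaK", "gNaCa", "gCaP", "gup",
)

#: Rectangular stimulus amplitude (pA/pF) used by default: twice the
#: diastolic threshold of the baseline AF cell for a 2-ms pulse, found
#: once by bisection (see :func:`diastolic_threshold`).
DEFAULT_STIM_AMPLITUDE = 2.0 * 12.5

SCALE_MIN, SCALE_MAX = 0.0, 3.0


@dataclass(frozen=True)
class CellParams:
    """Maximal-conductance vector of one virtual cell.

    ``cond`` follows the layout of :data:`afpom._crn.COND_NAMES`; the two
    trailing background conductances are never sampled.
    """

    cond: np.ndarray
    label: str = "af-baseline"

    def __post_init__(self):
        cond = np.asarray(self.cond, dtype=float)
        if cond.shape != (len(_crn.COND_NAMES),):
            raise ValidationError(
                f"cond must have shape ({len(_crn.COND_NAMES)},), got {cond.shape}")
        if np.any(cond < 0.0):
            raise ValidationError("maximal conductances must be >= 0")
        object.__setattr__(self, "cond", cond)

    @classmethod
    def af_baseline(cls) -> "CellParams":
        """The chronic-AF remodeled baseline cell."""
        return cls(_crn.af_baseline_cond(), label="af-baseline")

    @classmethod
    def control(cls) -> "CellParams":
        """The unremodeled (sinus-rhythm) cell."""
        return cls(_crn.CONTROL_COND.copy(), label="control")

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.cond[_crn.COND_NAMES.index(name)])
        except ValueError:
            raise ConfigurationError(f"unknown conductance {name!r}") from None

    def to_json(self) -> str:
        return json.dumps({"label": self.label,
                           "cond": dict(zip(_crn.COND_NAMES, self.cond))})

    @classmethod
    def from_json(cls, text: str) -> "CellParams":
        obj = json.loads(text)
        cond = np.array([obj["cond"][n] for n in _crn.COND_NAMES])
        return cls(cond, label=obj.get("label", "custom"))


def scale_conductances(
    base: CellParams,
    scale: Mapping[str, float] | Sequence[float] | np.ndarray,
    names: Sequence[str] = SAMPLED_CONDUCTANCES,
) -> CellParams:
    """Multiply the sampled maximal conductances of ``base`` elementwise.

    ``scale`` is either a mapping from conductance name to factor or a
    sequence aligned with ``names``.  Factors must lie in [0, 3]
    (−100%..+200% of nominal).  ``base`` is not modified.
    """
    if isinstance(scale, Mapping):
        items = list(scale.items())
    else:
        arr = np.asarray(scale, dtype=float)
        if arr.shape != (len(names),):
            raise ValidationError(
                f"scale must have length {len(names)}, got {arr.shape}")
        items = list(zip(names, arr))
    cond = base.cond.copy()
    for name, factor in items:
        if name not in _crn.COND_NAMES:
            raise ConfigurationError(f"unknown conductance {name!r}")
        if not (SCALE_MIN <= factor <= SCALE_MAX):
            raise ValidationError(
                f"scale factor for {name} must be in [{SCALE_MIN}, {SCALE_MAX}], "
                f"got {factor}")
        cond[_crn.COND_NAMES.index(name)] *= factor
    return CellParams(cond, label="scaled")


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic rectangular-pulse pacing.

    amplitude is in pA/pF (depolarizing positive); the product of pulse
    duration and frequency must leave a diastolic interval.
    """

    frequency_hz: float = 1.0
    amplitude: float = DEFAULT_STIM_AMPLITUDE
    pulse_ms: float = 2.0
    n_beats: int = 30

    def __post_init__(self):
        if self.frequency_hz <= 0:
            raise ValidationError("pacing frequency must be > 0")
        if self.pulse_ms * self.frequency_hz >= 1000.0:
            raise ValidationError("stimulus pulse longer than the pacing cycle")
        if self.n_beats < 1:
            raise ValidationError("need at least one beat")

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.frequency_hz


@dataclass
class VoltageTrace:
    """Uniformly sampled transmembrane voltage with stimulus onsets."""

    time: np.ndarray          # ms, uniform grid starting at 0
    v: np.ndarray             # mV
    stim_times: np.ndarray    # ms
    dt: float                 # sample interval, ms

    def __post_init__(self):
        if self.time.size == 0 or self.time.size != self.v.size:
            raise ValidationError("time and v must be equal-length, non-empty")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            f.create_dataset("V", data=self.v)
            f.create_dataset("stim_times", data=self.stim_times)
            f.attrs["dt"] = self.dt

    @classmethod
    def from_hdf5(cls, path) -> "VoltageTrace":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["time"][:], f["V"][:], f["stim_times"][:],
                       float(f.attrs["dt"]))

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.time, self.v]),
                   delimiter=",", header="time_ms,V_mV", comments="")


def derivatives(state: np.ndarray, params: CellParams, stim: float = 0.0) -> np.ndarray:
    """Time derivative of the 21-component state (reference path).

    Pure function of its inputs; raises on non-finite state or gates
    outside [0, 1].  Units: mV/ms for voltage, 1/ms for gates, mM/ms for
    concentrations.
    """
    return _crn.derivatives(np.asarray(state, dtype=float), params.cond, stim)


def resting_state() -> np.ndarray:
    """Published resting state used as the initial condition everywhere."""
    return _crn.initial_state()


def simulate_cell(
    params: CellParams,
    protocol: PacingProtocol = PacingProtocol(),
    duration_ms: float | None = None,
    dt: float = 0.02,
    sample_ms: float = 0.1,
    initial_state: np.ndarray | None = None,
) -> VoltageTrace:
    """Pace a single cell and return its voltage trace.

    The run is seed-free and bit-reproducible: identical inputs give
    identical traces.  ``duration_ms`` defaults to ``n_beats`` full
    cycles and must cover at least that many.
    """
    cycles_ms = protocol.n_beats * protocol.cycle_ms
    if duration_ms is None:
        duration_ms = cycles_ms
    elif duration_ms < cycles_ms:
        raise ValidationError("duration does not cover the requested beats")
    record_every = max(1, round(sample_ms / dt))
    n_steps = int(round(duration_ms / dt))
    # make the recorded grid exact
    n_steps -= n_steps % record_every
    state = (resting_state() if initial_state is None
             else np.asarray(initial_state, dtype=float).copy())[None, :]
    tab = _get_tables(dt)
    v = _crn.run_cell(
        state, dt, n_steps, params.cond, tab,
        0, int(round(protocol.cycle_ms / dt)), int(round(protocol.pulse_ms / dt)),
        protocol.amplitude, record_every)
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise SimulationError(
            f"solver diverged at t = {bad * record_every * dt:.3f} ms")
    time = np.arange(v.size) * (record_every * dt)
    stim_times = np.arange(protocol.n_beats) * protocol.cycle_ms
    stim_times = stim_times[stim_times < duration_ms]
    return VoltageTrace(time, v, stim_times, record_every * dt)


_TABLE_CACHE: dict[float, np.ndarray] = {}


def _get_tables(dt: float) -> np.ndarray:
    tab = _TABLE_CACHE.get(dt)
    if tab is None:
        tab = _TABLE_CACHE[dt] = _crn.build_tables(dt)
    return tab


def relax_to_rest(params: CellParams, duration_ms: float = 60_000.0,
                  dt: float = 0.02) -> np.ndarray:
    """Quiescent state after ``duration_ms`` of stimulus-free integration."""
    state = resting_state()[None, :].copy()
    n_steps = int(round(duration_ms / dt))
    _crn.run_cell(state, dt, n_steps, params.cond, _get_tables(dt),
                  n_steps + 1, n_steps + 1, 0, 0.0, n_steps)
    if not np.all(np.isfinite(state)):
        raise SimulationError("relaxation diverged")
    return state[0]


def diastolic_threshold(
    params: CellParams,
    pulse_ms: float = 2.0,
    dt: float = 0.02,
    tol: float = 0.25,
) -> float:
    """Diastolic stimulus threshold (pA/pF) by bisection from rest.

    A pulse is suprathreshold when the cell depolarizes beyond 0 mV
    within 50 ms.
    """

    def fires(amp: float) -> bool:
        proto = PacingProtocol(frequency_hz=20.0, amplitude=amp,
                               pulse_ms=pulse_ms, n_beats=1)
        trace = simulate_cell(params, proto, duration_ms=50.0, dt=dt)
        return bool(np.max(trace.v) > 0.0)

    lo, hi = 0.0, 64.0
    if not fires(hi):
        raise SimulationError("cell does not fire even at 64 pA/pF")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def limit_cycle_states(
    params: CellParams,
    cycle_ms: float = 250.0,
    n_beats: int = 8,
    dt: float = 0.02,
    sample_ms: float = 1.0,
    amplitude: float = DEFAULT_STIM_AMPLITUDE,
    pulse_ms: float = 2.0,
) -> np.ndarray:
    """Full-state samples over one paced cycle (used to seed spiral waves).

    Paces ``n_beats - 1`` conditioning beats, then records the complete
    21-component state every ``sample_ms`` over one further cycle.
    Returns an array of shape (cycle_ms/sample_ms, 21).
    """
    state = resting_state()[None, :].copy()
    tab = _get_tables(dt)
    per = int(round(cycle_ms / dt))
    _crn.run_cell(state, dt, (n_beats - 1) * per, params.cond, tab,
                  0, per, int(round(pulse_ms / dt)), amplitude, per)
    n_samples = int(round(cycle_ms / sample_ms))
    chunk = int(round(sample_ms / dt))
    out = np.empty((n_samples, _crn.N_STATES))
    pulse_steps = int(round(pulse_ms / dt))
    done = 0
    for k in range(n_samples):
        out[k] = state[0]
        amp = amplitude if done < pulse_steps else 0.0
        _crn.run_cell(state, dt, chunk, params.cond, tab, 0, 10 ** 9,
                      min(pulse_steps - done, chunk) if amp else 0, amp, chunk)
        done += chunk
    if not np.all(np.isfinite(out)):
        raise SimulationError("limit-cycle sampling diverged")
    return out
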