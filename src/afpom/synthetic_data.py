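"""Synthetic stand-ins for the experimental calibration data.

The population is calibrated against per-biomarker acceptance ranges
measured in patient trabeculae; no such dataset ships with the package,
so this module generates a configurable envelope instead, centered by
default on the phenotype of the baseline AF cell.  It also produces
closed-form synthetic AP traces (trapezoid or exponential-repolarization
shapes) whose true biomarkers are known exactly, used to validate the
biomarker extraction.

The default envelope (±30% of the baseline phenotype, all biomarkers,
all pacing rates) is a package choice, not an experimental result; real
ranges can be dropped in from YAML/JSON with the same schema.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import yaml

from .biomarkers import APBiomarkers, compute_ap_biomarkers, compute_rate_ratios
from .cell_model import CellParams, PacingProtocol, VoltageTrace, simulate_cell
from .errors import ValidationError

__all__ = ["BiomarkerRanges", "generate_biomarker_ranges", "default_ranges",
           "baseline_phenotype", "generate_synthetic_ap", "trapezoid_truth"]

DEFAULT_FREQS = (1.0, 2.0, 3.0, 4.0)
DEFAULT_SPREAD = 0.3


@dataclass(frozen=True)
class BiomarkerRanges:
    """Acceptance envelope: biomarker name -> (lo, hi).

    Keys are the 1-Hz biomarkers (``APD20`` … ``V20``) plus rate-ratio
    entries like ``APD90ratio_4Hz``.  Every interval must satisfy
    lo < hi.
    """

    bounds: dict

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"range for {name} is empty: [{lo}, {hi}]")

    def contains(self, record: dict) -> tuple[bool, list]:
        """Check a biomarker record; returns (accepted, failed keys).

        Keys of ``record`` missing from the envelope are ignored; a NaN
        value fails its check.
        """
        failed = []
        for name, (lo, hi) in self.bounds.items():
            value = record.get(name)
            if value is None:
                continue
            if not (np.isfinite(value) and lo <= value <= hi):
                failed.append(name)
        return (not failed, failed)

    def widened(self, factor: float) -> "BiomarkerRanges":
        """Envelope with every interval symmetric-widened by ``factor``."""
        out = {}
        for name, (lo, hi) in self.bounds.items():
            c, h = 0.5 * (lo + hi), 0.5 * (hi - lo)
            out[name] = (c - factor * h, c + factor * h)
        return BiomarkerRanges(out)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump({k: [float(lo), float(hi)]
                            for k, (lo, hi) in self.bounds.items()}, f)

    @classmethod
    def from_yaml(cls, path) -> "BiomarkerRanges":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls({k: (float(v[0]), float(v[1])) for k, v in raw.items()})


def generate_biomarker_ranges(
    center: dict,
    spread: float = DEFAULT_SPREAD,
    jitter: float = 0.0,
    seed: int | None = None,
) -> BiomarkerRanges:
    """Envelope of ±``spread``·|center| around each center value.

    With ``jitter`` > 0, each bound is additionally perturbed by a
    seeded uniform fraction of its half-width (deterministic given
    ``seed``).
    """
    if not 0.0 < spread <= 1.0:
        raise ValidationError("spread must be in (0, 1]")
    rng = np.random.default_rng(seed)
    bounds = {}
    for name, value in center.items():
        half = spread * abs(value)
        lo, hi = value - half, value + half
        if jitter > 0.0:
            lo -= jitter * half * rng.random()
            hi += jitter * half * rng.random()
        bounds[name] = (lo, hi)
    return BiomarkerRanges(bounds)


@functools.lru_cache(maxsize=4)
def baseline_phenotype(
    freqs: tuple = DEFAULT_FREQS,
    n_beats: int = 30,
    dt: float = 0.02,
) -> dict:
    """Biomarkers and rate ratios of the baseline AF cell (cached).

    The returned flat dict has the 1-Hz biomarkers under their plain
    names and the rate ratios under ``APD50ratio_fHz`` keys.
    """
    params = CellParams.af_baseline()
    by_freq = {}
    for f in freqs:
        trace = simulate_cell(params, PacingProtocol(frequency_hz=f,
                                                     n_beats=n_beats), dt=dt)
        by_freq[f] = compute_ap_biomarkers(trace)
    out = dict(by_freq[1.0].as_dict())
    out.update(compute_rate_ratios(by_freq).as_dict())
    return out


def default_ranges(spread: float = DEFAULT_SPREAD) -> BiomarkerRanges:
    """The package's default acceptance envelope (baseline ± spread)."""
    return generate_biomarker_ranges(baseline_phenotype(), spread=spread)


def trapezoid_truth(rest: float, amplitude: float, plateau_ms: float,
                    fall_ms: float) -> dict:
    """Closed-form biomarkers of the trapezoid AP shape."""
    return {
        "RMP": rest,
        "APA": amplitude,
        "APD20": plateau_ms + 0.2 * fall_ms,
        "APD50": plateau_ms + 0.5 * fall_ms,
        "APD90": plateau_ms + 0.9 * fall_ms,
        "V20": rest + amplitude,  # 0.2*APD90 < plateau for fall <= 4*plateau
    }


def generate_synthetic_ap(
    shape: str = "trapezoid",
    rest: float = -80.0,
    amplitude: float = 100.0,
    plateau_ms: float = 100.0,
    fall_ms: float = 200.0,
    t_rise: float = 50.0,
    duration_ms: float = 500.0,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> VoltageTrace:
    """Synthetic single-AP trace with closed-form true biomarkers.

    ``trapezoid``: instant rise at ``t_rise`` to rest+amplitude, flat
    plateau, linear fall back to rest (truth given by
    :func:`trapezoid_truth`).  ``exponential``: instant rise followed by
    exponential repolarization with time constant ``fall_ms``.  Optional
    additive white noise of standard deviation ``noise_sd`` mV, seeded.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    time = np.arange(0.0, duration_ms + dt / 2, dt)
    v = np.full(time.size, rest)
    tau = time - t_rise
    if shape == "trapezoid":
        on_plateau = (tau >= 0) & (tau <= plateau_ms)
        falling = (tau > plateau_ms) & (tau <= plateau_ms + fall_ms)
        v[on_plateau] = rest + amplitude
        v[falling] = rest + amplitude * (1.0 - (tau[falling] - plateau_ms) / fall_ms)
    elif shape == "exponential":
        up = tau >= 0
        v[up] = rest + amplitude * np.exp(-tau[up] / fall_ms)
    else:
        raise ValidationError(f"unknown shape {shape!r}")
    if noise_sd > 0.0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, v.size)
    return VoltageTrace(time, v, np.array([t_rise]), dt)
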