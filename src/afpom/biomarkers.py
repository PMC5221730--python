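"""Action-potential biomarkers and rate-dependence ratios.

Biomarkers quantified on a single paced beat (conventions follow common
microelectrode practice):

* RMP — resting membrane potential, the voltage immediately before the
  stimulus;
* APA — amplitude, peak voltage minus RMP;
* APDx — duration from the take-off point (maximum dV/dt during the
  upstroke) to the repolarization crossing of RMP + (1 − x/100)·APA,
  linearly interpolated between samples;
* V20 — plateau potential, the voltage at take-off + 0.2·APD90.

Rate dependence is summarized as the ratio of APD50/APD90 at 2, 3 and
4 Hz to their 1-Hz values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_model import VoltageTrace
from .errors import ValidationError

__all__ = ["APBiomarkers", "RateRatios", "compute_ap_biomarkers",
           "compute_rate_ratios", "biomarker_frame"]

#: an AP with amplitude below this (mV) is flagged not-excited
MIN_APA = 10.0
#: ... or whose peak stays below this (mV): a sub-threshold or purely
#: Ca-mediated hump is not a regenerative upstroke
MIN_PEAK = -20.0

BIOMARKER_NAMES = ("APD20", "APD50", "APD90", "APA", "RMP", "V20")


@dataclass(frozen=True)
class APBiomarkers:
    """Single-beat biomarkers; values are NaN when ``excited`` is False,
    and APDs are NaN when ``repolarized`` is False (threshold never
    recrossed, e.g. alternans or repolarization failure)."""

    apd20: float
    apd50: float
    apd90: float
    apa: float
    rmp: float
    v20: float
    excited: bool = True
    repolarized: bool = True

    def as_dict(self) -> dict:
        return {"APD20": self.apd20, "APD50": self.apd50, "APD90": self.apd90,
                "APA": self.apa, "RMP": self.rmp, "V20": self.v20}

    def __post_init__(self):
        if self.excited and self.repolarized:
            if not (0.0 < self.apd20 <= self.apd50 <= self.apd90):
                raise ValidationError(
                    f"APD ordering violated: {self.apd20}, {self.apd50}, {self.apd90}")
            if self.apa <= 0:
                raise ValidationError("APA must be positive for an excited beat")


NOT_EXCITED = APBiomarkers(*(math.nan,) * 6, excited=False, repolarized=False)


@dataclass(frozen=True)
class RateRatios:
    """APD(f)/APD(1 Hz) for f in the tested frequencies (Hz)."""

    apd50: dict
    apd90: dict

    def as_dict(self) -> dict:
        out = {}
        for f in sorted(self.apd50):
            out[f"APD50ratio_{f:g}Hz"] = self.apd50[f]
        for f in sorted(self.apd90):
            out[f"APD90ratio_{f:g}Hz"] = self.apd90[f]
        return out


def _interp_crossing(t0, v0, t1, v1, level):
    """Time at which the segment (t0,v0)-(t1,v1) crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _crossing_time(seg_t, seg_v, k, level, dt):
    """Downward crossing time of ``level`` near first-passage index ``k``.

    A least-squares line over a ±1 ms window around the first sample
    below the level gives a crossing estimate that is exact on linear
    repolarization segments and unbiased under additive noise (plain
    two-sample interpolation is early-biased when the trace is noisy).
    """
    half = max(1, int(round(1.0 / dt)))
    lo, hi = max(k - half, 0), min(k + half + 1, seg_t.size)
    tt, vv = seg_t[lo:hi], seg_v[lo:hi]
    if tt.size >= 3:
        slope, intercept = np.polyfit(tt, vv, 1)
        if slope < 0.0:
            t_cross = (level - intercept) / slope
            # noise shifts the first-passage sample early, so allow the
            # fitted crossing to sit a few ms past the window
            if tt[0] - 4.0 <= t_cross <= tt[-1] + 4.0:
                return float(t_cross)
    return _interp_crossing(seg_t[k - 1], seg_v[k - 1],
                            seg_t[k], seg_v[k], level)


def compute_ap_biomarkers(trace: VoltageTrace, beat: int = -1) -> APBiomarkers:
    """Biomarkers of one stimulated beat of ``trace``.

    ``beat`` indexes ``trace.stim_times`` (default: last beat).  The beat
    window runs from its stimulus onset to the next onset (or the end of
    the trace) and must contain a single AP returning toward rest.
    """
    if trace.stim_times.size == 0:
        raise ValidationError("trace has no stimulus onsets")
    onsets = np.asarray(trace.stim_times, dtype=float)
    idx = range(len(onsets))[beat]
    t_on = onsets[idx]
    t_end = onsets[idx + 1] if idx + 1 < len(onsets) else trace.time[-1]

    i_on = int(np.searchsorted(trace.time, t_on - 1e-9))
    i_end = int(np.searchsorted(trace.time, t_end + 1e-9))
    seg_t = trace.time[max(i_on - 1, 0):i_end]
    seg_v = trace.v[max(i_on - 1, 0):i_end]
    if seg_t.size < 4:
        raise ValidationError("beat window too short")

    rmp = float(seg_v[0])  # immediately pre-stimulus
    i_peak = int(np.argmax(seg_v))
    apa = float(seg_v[i_peak] - rmp)
    if apa < MIN_APA or seg_v[i_peak] < MIN_PEAK:
        return NOT_EXCITED

    # take-off: right endpoint of the steepest upstroke interval
    dv = np.diff(seg_v[:i_peak + 1])
    if dv.size == 0:
        return NOT_EXCITED
    i_take = int(np.argmax(dv)) + 1
    t_take = float(seg_t[i_take])

    apds = {}
    repolarized = True
    for frac, name in ((0.20, "APD20"), (0.50, "APD50"), (0.90, "APD90")):
        level = rmp + (1.0 - frac) * apa
        below = np.flatnonzero(seg_v[i_peak:] < level)
        if below.size == 0:
            repolarized = False
            apds[name] = math.nan
            continue
        k = i_peak + below[0]
        t_cross = _crossing_time(seg_t, seg_v, k, level,
                                 float(seg_t[1] - seg_t[0]))
        apds[name] = t_cross - t_take
    if not repolarized:
        return APBiomarkers(math.nan, math.nan, math.nan, apa, rmp, math.nan,
                            excited=True, repolarized=False)

    v20 = float(np.interp(t_take + 0.2 * apds["APD90"], seg_t, seg_v))
    return APBiomarkers(apds["APD20"], apds["APD50"], apds["APD90"],
                        apa, rmp, v20)


def compute_rate_ratios(bm_by_freq: dict) -> RateRatios:
    """Elementwise APD(f)/APD(1 Hz) for every non-reference frequency.

    ``bm_by_freq`` maps pacing frequency (Hz) to :class:`APBiomarkers`
    and must contain the 1-Hz reference with valid APDs.
    """
    if 1 not in bm_by_freq and 1.0 not in bm_by_freq:
        raise ValidationError("rate ratios need the 1-Hz reference biomarkers")
    ref = bm_by_freq.get(1, bm_by_freq.get(1.0))
    if not (ref.excited and ref.repolarized) or ref.apd50 == 0 or ref.apd90 == 0:
        raise ValidationError("1-Hz biomarkers invalid or zero")
    r50, r90 = {}, {}
    for f, bm in bm_by_freq.items():
        if float(f) == 1.0:
            continue
        r50[float(f)] = bm.apd50 / ref.apd50
        r90[float(f)] = bm.apd90 / ref.apd90
    return RateRatios(r50, r90)


def biomarker_frame(records: dict) -> pd.DataFrame:
    """Tidy table with one row per (model, frequency).

    ``records`` maps model id to a dict mapping frequency to
    :class:`APBiomarkers`.
    """
    rows = []
    for model_id, by_freq in records.items():
        for f, bm in sorted(by_freq.items()):
            rows.append({"model": model_id, "frequency_hz": float(f),
                         **{k.lower(): v for k, v in bm.as_dict().items()},
                         "excited": bm.excited, "repolarized": bm.repolarized})
    return pd.DataFrame(rows)
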