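"""Build and calibrate the population of virtual AF cells.

Candidate models are Latin-hypercube samples of the eleven conductance
scale factors over [0, 3] (−100%..+200% of the remodeled nominal
values).  Each candidate is paced at 1–4 Hz, its biomarkers and rate
ratios are extracted, and it is accepted into the population iff every
biomarker at every tested frequency lies inside the experimental (here:
synthetic) acceptance envelope.  Models that fail to excite, fail to
repolarize, or crash the solver are rejected with a recorded reason,
never aborting the sweep.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .biomarkers import compute_ap_biomarkers, compute_rate_ratios
from .cell_model import (SAMPLED_CONDUCTANCES, CellParams, PacingProtocol,
                         scale_conductances, simulate_cell)
from .errors import AfpomError, ValidationError
from .synthetic_data import DEFAULT_FREQS, BiomarkerRanges, default_ranges

__all__ = ["latin_hypercube_sample", "evaluate_candidate",
           "evaluate_population", "calibrate_population", "build_population"]

log = logging.getLogger(__name__)

SCALE_COLUMNS = tuple(f"s_{name}" for name in SAMPLED_CONDUCTANCES)


def latin_hypercube_sample(
    n: int,
    dims: int = len(SAMPLED_CONDUCTANCES),
    lo: float = 0.0,
    hi: float = 3.0,
    seed: int | None = None,
) -> np.ndarray:
    """(n, dims) Latin hypercube sample of scale factors in [lo, hi].

    Each dimension places exactly one sample in each of the n
    equal-width strata; reproducible given ``seed``.
    """
    if n < 1:
        raise ValidationError("sample count must be >= 1")
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    return qmc.scale(sampler.random(n), [lo] * dims, [hi] * dims)


def evaluate_candidate(
    scale: Sequence[float],
    freqs: Sequence[float] = DEFAULT_FREQS,
    n_beats: int = 30,
    dt: float = 0.02,
    base: CellParams | None = None,
) -> dict:
    """Phenotype record of one candidate scale vector.

    Returns a flat dict with the scale factors, per-frequency biomarkers
    (``APD90@2Hz`` style keys), 1-Hz biomarkers under their plain names,
    rate ratios, and ``ok``/``failure`` flags.  Deterministic; never
    raises for solver or phenotype pathologies.
    """
    base = base or CellParams.af_baseline()
    record = dict(zip(SCALE_COLUMNS, np.asarray(scale, dtype=float)))
    record["ok"] = False
    record["failure"] = ""
    by_freq = {}
    try:
        params = scale_conductances(base, scale)
        for f in freqs:
            trace = simulate_cell(
                params, PacingProtocol(frequency_hz=f, n_beats=n_beats), dt=dt)
            bm = compute_ap_biomarkers(trace)
            by_freq[float(f)] = bm
            for name, value in bm.as_dict().items():
                record[f"{name}@{f:g}Hz"] = value
            if not bm.excited:
                record["failure"] = f"not excited at {f:g} Hz"
                return record
            if not bm.repolarized:
                record["failure"] = f"no repolarization at {f:g} Hz"
                return record
        record.update(by_freq[1.0].as_dict())
        record.update(compute_rate_ratios(by_freq).as_dict())
        record["ok"] = True
    except AfpomError as exc:
        record["failure"] = f"{type(exc).__name__}: {exc}"
    return record


def evaluate_population(
    scales: np.ndarray,
    freqs: Sequence[float] = DEFAULT_FREQS,
    n_beats: int = 30,
    dt: float = 0.02,
    progress: bool = False,
) -> pd.DataFrame:
    """Evaluate every candidate row of ``scales``; one record per row.

    Rows are independent (no shared mutable state), so results do not
    depend on evaluation order.
    """
    iterator = range(scales.shape[0])
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="evaluating candidates")
    records = [evaluate_candidate(scales[i], freqs, n_beats, dt)
               for i in iterator]
    df = pd.DataFrame(records)
    df.insert(0, "model", np.arange(len(df)))
    return df


def calibrate_population(table: pd.DataFrame,
                         ranges: BiomarkerRanges) -> pd.DataFrame:
    """Flag each candidate accepted iff all biomarkers are in range.

    Adds ``accepted`` and ``rejection_reason`` columns; logs the
    acceptance count and a per-biomarker rejection tally.
    """
    missing = [c for c in ("ok",) if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks columns {missing}; "
                              "run evaluate_population first")
    accepted = np.zeros(len(table), dtype=bool)
    reasons = []
    tally: dict = {}
    for i, row in table.iterrows():
        if not row["ok"]:
            reasons.append(row["failure"] or "evaluation failure")
            continue
        ok, failed = ranges.contains(row.to_dict())
        accepted[i] = ok
        reasons.append("" if ok else "out of range: " + ",".join(failed))
        for name in failed:
            tally[name] = tally.get(name, 0) + 1
    out = table.copy()
    out["accepted"] = accepted
    out["rejection_reason"] = reasons
    log.info("calibration: %d/%d accepted; rejection tally: %s",
             accepted.sum(), len(table), tally)
    return out


def build_population(
    n: int = 512,
    seed: int | None = None,
    ranges: BiomarkerRanges | None = None,
    freqs: Sequence[float] = DEFAULT_FREQS,
    n_beats: int = 30,
    dt: float = 0.02,
    progress: bool = False,
) -> pd.DataFrame:
    """Sample, evaluate and calibrate a population in one call."""
    scales = latin_hypercube_sample(n, seed=seed)
    table = evaluate_population(scales, freqs, n_beats, dt, progress=progress)
    return calibrate_population(table, ranges or default_ranges())
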