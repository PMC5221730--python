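"""Shared fixtures.

Expensive artifacts (baseline traces, evaluated mini-populations, the
scaled-down trend experiment) are session-scoped so every test reuses
one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from afpom.cell_model import CellParams, PacingProtocol, simulate_cell
from afpom.population import evaluate_population, latin_hypercube_sample


@pytest.fixture(scope="session")
def baseline_params() -> CellParams:
    return CellParams.af_baseline()


@pytest.fixture(scope="session")
def baseline_trace_1hz(baseline_params):
    """30-beat 1-Hz pacing of the baseline AF cell."""
    return simulate_cell(baseline_params, PacingProtocol(frequency_hz=1.0))


@pytest.fixture(scope="session")
def baseline_traces_by_freq(baseline_params, baseline_trace_1hz):
    out = {1.0: baseline_trace_1hz}
    for f in (2.0, 3.0, 4.0):
        out[f] = simulate_cell(baseline_params,
                               PacingProtocol(frequency_hz=f))
    return out


@pytest.fixture(scope="session")
def evaluated_mini_population():
    """16 evaluated candidates (phenotypes at 1-4 Hz), fixed seed."""
    scales = latin_hypercube_sample(16, seed=2024)
    return evaluate_population(scales)


@pytest.fixture(scope="session")
def trend_experiment():
    """The scaled-down maintenance + ICaL-block experiment (fixed seed)."""
    from afpom.pipeline import (PRESETS, run_ical_block_experiment,
                                run_maintenance_experiment)

    cfg = PRESETS["mini"]
    base = run_maintenance_experiment(cfg)
    block = run_ical_block_experiment(cfg, base)
    return base, block


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
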