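"""End-to-end experiments on the calibrated population.

Two experiments mirror the study design:

* **maintenance** — one reentry simulation per calibrated model on the
  configured mesh; models are split into sustained vs unsustained
  groups, each conductance is compared between groups (Mann–Whitney,
  α = .01), and DF/RM are related to the conductances by partial
  correlation among the sustained models.
* **ICaL block** — every model sustained at baseline is continued from
  its end-of-baseline state with gCaL halved; ΔDF, ΔRM and
  block-induced termination are measured, terminated vs persisting
  groups are compared, and the Δs are related to the conductances.

All stages are deterministic given the configuration seed; completed
tissue simulations are cached on disk (keyed by a content hash of the
configuration and scale vector) so interrupted runs resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_model import CellParams, scale_conductances
from .errors import AfpomError, ConfigurationError, ValidationError
from .population import SCALE_COLUMNS, build_population
from .rotor_analysis import reentry_biomarkers
from .stats_report import (build_group_comparison, partial_correlation_table,
                           signed_r_squared)
from .synthetic_data import default_ranges
from .tissue_sim import BlockSpec, build_mesh, initiate_reentry, run_tissue

__all__ = ["ExperimentConfig", "MaintenanceResult", "BlockResult",
           "run_maintenance_experiment", "run_ical_block_experiment", "PRESETS"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one population experiment.

    ``scale_tag`` records the intent: ``mini`` (continuous-integration
    size), ``desk`` (single-workstation size) or ``study`` (full-size,
    cluster-scale).
    """

    n_candidates: int = 256
    seed: int = 1
    envelope_spread: float = 0.5
    mesh_kind: str = "sphere"
    mesh_size: float = 3.2          # cm (sheet side / torus period)
    sphere_radius: float = 0.9      # cm (desk scale; study scale uses 2.5)
    sphere_subdivisions: int = 4
    dx: float = 0.05                # cm
    dcoef: float = 1.0e-3           # cm^2/ms
    dt_tissue: float = 0.04         # ms
    baseline_ms: float = 2000.0
    block_ms: float = 2000.0
    block: tuple = ("gCaL", 0.5)
    init_method: str = "phase_seed"
    skip_ms: float = 500.0
    freqs: tuple = (1.0, 2.0, 3.0, 4.0)
    n_beats: int = 30
    dt_cell: float = 0.02
    outdir: str | None = None
    scale_tag: str = "desk"

    def content_hash(self) -> str:
        payload = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)
                   if f.name not in ("outdir",)}
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


#: named configurations; ``study`` approximates the original scale and is
#: far beyond a single desk session.
PRESETS = {
    "mini": ExperimentConfig(n_candidates=192, baseline_ms=2000.0,
                             block_ms=2000.0, scale_tag="mini"),
    "desk": ExperimentConfig(n_candidates=256, scale_tag="desk"),
    "study": ExperimentConfig(n_candidates=16384, envelope_spread=0.3,
                              mesh_kind="sphere", sphere_radius=2.5,
                              sphere_subdivisions=6, baseline_ms=7000.0,
                              block_ms=7000.0, scale_tag="study"),
}


@dataclass
class MaintenanceResult:
    config: ExperimentConfig
    population: pd.DataFrame          # full candidate table with accepted flag
    results: pd.DataFrame             # one row per accepted model
    comparison: pd.DataFrame | None   # sustained vs unsustained, per factor
    pcr: pd.DataFrame | None          # factor x (DF, RM), sustained models
    df_rm_r2: float | None
    final_states: dict = field(default_factory=dict, repr=False)


@dataclass
class BlockResult:
    config: ExperimentConfig
    results: pd.DataFrame             # one row per model sustained at baseline
    comparison: pd.DataFrame | None   # terminated vs persisting, per factor
    pcr: pd.DataFrame | None          # factor x (dDF, dRM), persisting models
    mean_delta_rm: float
    delta_df_rm_r2: float | None


def _build_cfg_mesh(cfg: ExperimentConfig):
    if cfg.mesh_kind == "sphere":
        return build_mesh("sphere", radius=cfg.sphere_radius,
                          subdivisions=cfg.sphere_subdivisions)
    return build_mesh(cfg.mesh_kind, size=cfg.mesh_size, dx=cfg.dx)


class _Cache:
    """JSON row cache keyed by (config hash, phase, model scales)."""

    def __init__(self, outdir: str | None, cfg_hash: str):
        self.path = (Path(outdir) / f"cache_{cfg_hash}.json"
                     if outdir else None)
        self.rows = {}
        if self.path and self.path.exists():
            self.rows = json.loads(self.path.read_text())

    def key(self, phase: str, scales) -> str:
        blob = phase + ",".join(f"{s:.12g}" for s in scales)
        return hashlib.sha1(blob.encode()).hexdigest()[:16]

    def get(self, key):
        return self.rows.get(key)

    def put(self, key, row: dict) -> None:
        self.rows[key] = row
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text(json.dumps(self.rows))

    def states_path(self, key) -> Path | None:
        if self.path is None:
            return None
        return self.path.with_name(f"states_{key}.npz")


def _simulate_model(cfg, mesh, scales, block=None, init_states=None):
    params = scale_conductances(CellParams.af_baseline(), scales)
    if init_states is None:
        init_states = initiate_reentry(mesh, params, method=cfg.init_method,
                                       dt=cfg.dt_tissue, dcoef=cfg.dcoef)
        duration = cfg.baseline_ms
    else:
        duration = cfg.block_ms
    movie = run_tissue(mesh, params, init_states, duration_ms=duration,
                       dt=cfg.dt_tissue, dcoef=cfg.dcoef, block=block)
    rb = reentry_biomarkers(movie, skip_ms=cfg.skip_ms)
    return movie, rb


def run_maintenance_experiment(cfg: ExperimentConfig,
                               progress: bool = False) -> MaintenanceResult:
    """Experiment 1: reentry maintenance across the calibrated population."""
    ranges = default_ranges(spread=cfg.envelope_spread)
    population = build_population(cfg.n_candidates, seed=cfg.seed,
                                  ranges=ranges, freqs=cfg.freqs,
                                  n_beats=cfg.n_beats, dt=cfg.dt_cell,
                                  progress=progress)
    accepted = population[population.accepted].reset_index(drop=True)
    if len(accepted) == 0:
        raise ValidationError("calibration produced an empty population")
    log.info("maintenance experiment: %d calibrated models", len(accepted))
    mesh = _build_cfg_mesh(cfg)
    cache = _Cache(cfg.outdir, cfg.content_hash())
    rows = []
    final_states = {}
    iterator = accepted.iterrows()
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="tissue simulations")
    for _, model in iterator:
        scales = model[list(SCALE_COLUMNS)].to_numpy(float)
        row = {"model": int(model["model"]),
               **dict(zip(SCALE_COLUMNS, scales)),
               "seed": cfg.seed, "config": cfg.content_hash()}
        key = cache.key("baseline", scales)
        hit = cache.get(key)
        spath = cache.states_path(key)
        # the block experiment continues from the baseline end state, so a
        # cache hit is only usable when that state was persisted too
        usable = hit is not None and (hit.get("error")
                                      or (spath is not None and spath.exists()))
        if usable:
            row.update(hit)
            if not hit.get("error"):
                final_states[int(model["model"])] = np.load(spath)["states"]
        else:
            try:
                movie, rb = _simulate_model(cfg, mesh, scales)
                measured = {"DF": rb.df_hz, "RM": rb.rm_cm2,
                            "sustained": bool(rb.sustained),
                            "termination_ms": rb.termination_ms,
                            "mechanism": rb.mechanism, "error": ""}
                final_states[int(model["model"])] = movie.final_states
                if spath is not None:
                    np.savez_compressed(spath, states=movie.final_states)
            except AfpomError as exc:
                measured = {"DF": np.nan, "RM": np.nan, "sustained": False,
                            "termination_ms": None, "mechanism": "",
                            "error": f"{type(exc).__name__}: {exc}"}
            row.update(measured)
            cache.put(key, measured)
        rows.append(row)
    results = pd.DataFrame(rows)
    ok = results[results.error == ""]
    comparison = pcr = None
    df_rm_r2 = None
    factors = list(SCALE_COLUMNS)
    try:
        comparison = build_group_comparison(ok, "sustained", factors)
    except ValidationError as exc:
        log.warning("group comparison skipped: %s", exc)
    sustained = ok[ok.sustained]
    if len(sustained) >= len(factors) + 2:
        pcr = partial_correlation_table(sustained, factors, ["DF", "RM"])
        df_rm_r2 = signed_r_squared(sustained.DF, sustained.RM)
    else:
        log.warning("too few sustained models (%d) for partial correlation",
                    len(sustained))
    out = MaintenanceResult(cfg, population, results, comparison, pcr,
                            df_rm_r2, final_states)
    _write_outputs(cfg, "maintenance", results=results,
                   comparison=comparison, pcr=pcr)
    return out


def run_ical_block_experiment(cfg: ExperimentConfig,
                              baseline: MaintenanceResult,
                              progress: bool = False) -> BlockResult:
    """Experiment 2: conductance block on the models sustained at baseline.

    The block (default 50% gCaL) is applied from the end of each
    baseline run onward and the reentry is followed for ``block_ms``.
    A multiplier of 1.0 is the null intervention and changes nothing.
    """
    name, multiplier = cfg.block
    block = BlockSpec(name, multiplier, onset_ms=0.0)
    mesh = _build_cfg_mesh(cfg)
    ok = baseline.results[(baseline.results.error == "")
                          & baseline.results.sustained]
    if len(ok) == 0:
        raise ValidationError("no sustained baseline models to block")
    rows = []
    iterator = ok.iterrows()
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="block simulations")
    for _, model in iterator:
        scales = model[list(SCALE_COLUMNS)].to_numpy(float)
        mid = int(model["model"])
        row = {"model": mid, **dict(zip(SCALE_COLUMNS, scales)),
               "DF_base": model.DF, "RM_base": model.RM,
               "seed": cfg.seed, "config": cfg.content_hash()}
        try:
            movie, rb = _simulate_model(cfg, mesh, scales, block=block,
                                        init_states=baseline.final_states[mid])
            row.update({"DF_block": rb.df_hz, "RM_block": rb.rm_cm2,
                        "terminated": not rb.sustained,
                        "termination_ms": rb.termination_ms,
                        "mechanism": rb.mechanism, "error": ""})
        except AfpomError as exc:
            row.update({"DF_block": np.nan, "RM_block": np.nan,
                        "terminated": False, "termination_ms": None,
                        "mechanism": "",
                        "error": f"{type(exc).__name__}: {exc}"})
        rows.append(row)
    results = pd.DataFrame(rows)
    okb = results[results.error == ""].copy()
    okb["dDF"] = okb.DF_block - okb.DF_base
    okb["dRM"] = okb.RM_block - okb.RM_base
    results = results.merge(okb[["model", "dDF", "dRM"]], on="model",
                            how="left")
    factors = list(SCALE_COLUMNS)
    comparison = pcr = None
    delta_r2 = None
    try:
        comparison = build_group_comparison(okb, "terminated", factors)
    except ValidationError as exc:
        log.warning("responder comparison skipped: %s", exc)
    persisting = okb[~okb.terminated]
    if len(persisting) >= len(factors) + 2:
        pcr = partial_correlation_table(persisting, factors, ["dDF", "dRM"])
        delta_r2 = signed_r_squared(persisting.dDF, persisting.dRM)
    mean_drm = float(persisting.dRM.mean()) if len(persisting) else float("nan")
    out = BlockResult(cfg, results, comparison, pcr, mean_drm, delta_r2)
    _write_outputs(cfg, "block", results=results, comparison=comparison,
                   pcr=pcr)
    return out


def _write_outputs(cfg: ExperimentConfig, stem: str, **tables) -> None:
    if cfg.outdir is None:
        return
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg),
                "config_hash": cfg.content_hash(), "seed": cfg.seed}
    (outdir / f"{stem}_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    for name, tbl in tables.items():
        if tbl is not None:
            tbl.to_csv(outdir / f"{stem}_{name}.csv")
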