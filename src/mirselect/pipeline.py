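"""End-to-end workflow: load or simulate → preprocess → split → select →
three-stage tuning → final report.

One global seed is fanned out to each stage through a stable hash of the
stage name, so any stage can be rerun in isolation and reproduce the full
run's behaviour. A plain-text trace records every decision the staged
protocol makes (chosen chain, chosen strategy, chosen spec) plus a hash of
the prediction set, which appears exactly once before the final evaluation —
the leakage guard.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .modeling_eval import (
    Stage1Row, Stage2Row, Stage3Result, make_folds, stage1_compare,
    stage2_light_tune, stage3_fine_tune,
)
from .partition import SplitResult, kennard_stone_split, spxy_split
from .spectral_data import Dataset, align, read_references, read_spectra
from .synthetic_mir import SimConfig, SimTruth, simulate_dataset
from .variable_selection import SelectionResult, StrategyPoolConfig, build_strategy_pool

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stage_seed",
           "hybrid_recovery_run", "HybridRecoveryRun"]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; either file inputs or a simulate block."""

    spectra_path: str | None = None
    references_path: str | None = None
    simulate: SimConfig | None = None
    preproc_method_id: int = 9       # MSC + SG first derivative
    screen_chains: bool = False      # rank all ten chains and adopt the winner
    split_method: str = "spxy"
    split_fraction: float = 0.8
    cv_k: int = 5
    run_stage2: bool = True
    run_stage3: bool = True
    stage3_budget: int = 60
    cars_iterations: int = 50
    cars_mc_runs: int = 10
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulate is None and (self.spectra_path is None
                                      or self.references_path is None):
            raise ValueError("need either input paths or a simulate block")
        if self.split_method not in ("spxy", "ks"):
            raise ValueError("split_method must be 'spxy' or 'ks'")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (vars(v) if isinstance(v, SimConfig) else v)
             for k, v in vars(self).items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: Dataset
    truth: SimTruth | None
    chain: pp.PreprocChain
    screen_rows: list | None
    split: SplitResult
    pool: list[SelectionResult]
    stage1_rows: list[Stage1Row]
    selected: SelectionResult
    stage2_rows: list[Stage2Row] | None
    stage3: Stage3Result | None
    trace: list[str] = field(default_factory=list)


def _prediction_set_hash(ds_test: Dataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ds_test.X).tobytes())
    h.update(np.ascontiguousarray(ds_test.y).tobytes())
    return h.hexdigest()[:16]


def _preprocessed_dataset(ds: Dataset, chain: pp.PreprocChain,
                          ref_rows: np.ndarray | None = None) -> Dataset:
    """Apply a chain; the MSC reference comes from ``ref_rows`` (default: all)."""
    grid = ds.spectra.grid
    ref = None
    if chain.needs_msc_reference:
        rows = ds.X if ref_rows is None else ds.X[ref_rows]
        ref = pp.msc_fit(rows)
    return ds.with_X(pp.apply_chain(ds.X, chain, grid, ref))


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full workflow and (optionally) write its report CSVs.

    Order: load/simulate → provisional preprocessing (full-set MSC reference,
    used only for the deterministic split) → split → optional preprocessing
    screen on the split → re-preprocess with the calibration-only MSC
    reference → strategy pool → stage 1 (frozen booster) → stage 2 (light
    per-family tuning of the stage-1 winner) → stage 3 (fine tuning) →
    reports.
    """
    trace: list[str] = [f"config_hash={cfg.config_hash()}", f"seed={cfg.seed}"]

    # ---- inputs -----------------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        if sim_cfg.seed != stage_seed(cfg.seed, "simulate"):
            sim_cfg = SimConfig(**{**vars(sim_cfg),
                                   "seed": stage_seed(cfg.seed, "simulate")})
        ds, truth = simulate_dataset(sim_cfg)
        trace.append(f"simulate n={ds.n_samples} p={ds.spectra.n_wavenumbers} "
                     f"seed={sim_cfg.seed}")
    else:
        ds = align(read_spectra(cfg.spectra_path),
                   read_references(cfg.references_path))
        trace.append(f"loaded n={ds.n_samples} p={ds.spectra.n_wavenumbers}")

    # ---- provisional preprocessing + split --------------------------------
    chain = pp.get_chain(cfg.preproc_method_id)
    ds_pre = _preprocessed_dataset(ds, chain)
    splitter = spxy_split if cfg.split_method == "spxy" else kennard_stone_split
    split = splitter(ds_pre, cfg.split_fraction)
    trace.append(f"split method={cfg.split_method} cal={split.n_calibration} "
                 f"pred={split.n_prediction}")

    # ---- optional preprocessing screen ------------------------------------
    screen_rows = None
    if cfg.screen_chains:
        folds = make_folds(split.n_calibration, cfg.cv_k,
                           seed=stage_seed(cfg.seed, "screen"))
        raw_cal = ds.subset(split.calibration_ids)
        raw_test = ds.subset(split.prediction_ids)
        screen_rows = pp.screen_preprocessing(raw_cal, raw_test, folds)
        chain = screen_rows[0].chain
        trace.append(f"screen winner method_id={chain.method_id} ({chain.name})")

    # ---- final preprocessing with calibration-only MSC reference ----------
    cal_rows = np.array([ds.sample_ids.index(s) for s in split.calibration_ids])
    ds_final = _preprocessed_dataset(ds, chain, ref_rows=cal_rows)
    ds_cal = ds_final.subset(split.calibration_ids)
    ds_test = ds_final.subset(split.prediction_ids)
    trace.append(f"preprocess chain method_id={chain.method_id} ({chain.name})")
    trace.append(f"prediction_set_hash={_prediction_set_hash(ds_test)}")

    # ---- strategy pool + stage 1 ------------------------------------------
    pool_cfg = StrategyPoolConfig(
        cv_seed=stage_seed(cfg.seed, "folds"),
        forest_seed=stage_seed(cfg.seed, "forest"),
        cars_seed=stage_seed(cfg.seed, "cars"),
        cars_iterations=cfg.cars_iterations,
        cars_mc_runs=cfg.cars_mc_runs,
    )
    pool, profiles = build_strategy_pool(ds_cal.X, ds_cal.y, pool_cfg)
    for sel in pool:
        trace.append(f"strategy {sel.label}: {sel.cardinality} variables "
                     f"({sel.reduction:.1f}% reduction)"
                     + (" [empty]" if sel.is_empty else ""))
    stage1_rows = stage1_compare(pool, ds_cal, ds_test,
                                 seed=stage_seed(cfg.seed, "stage1"))
    winner_label = stage1_rows[0].label
    selected = next(s for s in pool if s.label == winner_label)
    trace.append(f"stage1 winner={winner_label} "
                 f"variables={selected.cardinality}")

    # ---- stages 2 and 3 ---------------------------------------------------
    folds = make_folds(ds_cal.n_samples, cfg.cv_k,
                       seed=stage_seed(cfg.seed, "folds"))
    stage2_rows = None
    if cfg.run_stage2:
        stage2_rows = stage2_light_tune(selected.mask, ds_cal, ds_test, folds,
                                        seed=stage_seed(cfg.seed, "stage2"))
        for row in stage2_rows:
            if row.test_report:
                trace.append(f"stage2 {row.family}: cv_rmse={row.cv_report.rmse:.4f} "
                             f"test_rpd={row.test_report.rpd:.4f}")
    stage3 = None
    if cfg.run_stage3:
        stage3 = stage3_fine_tune(selected.mask, ds_cal, ds_test, folds,
                                  budget=cfg.stage3_budget,
                                  seed=stage_seed(cfg.seed, "stage3"))
        trace.append(f"stage3 spec={dict(stage3.spec.params)}")
        trace.append(f"stage3 cv_r2={stage3.cv_report.r2:.4f} "
                     f"test_r2={stage3.test_report.r2:.4f} "
                     f"test_rpd={stage3.test_report.rpd:.4f} "
                     f"({stage3.test_report.williams})")

    result = PipelineResult(cfg, ds_final, truth, chain, screen_rows, split,
                            pool, stage1_rows, selected, stage2_rows, stage3,
                            trace)
    if cfg.out_dir is not None:
        write_reports(result, Path(cfg.out_dir))
    return result


# ---------------------------------------------------------------------------
# Scaled recovery study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HybridRecoveryRun:
    """One seed of the scaled simulator study: selection recovery + models."""

    seed: int
    n_selected: int
    precision: float
    recall: float
    vip08_precision: float
    stage2_test_rpd: dict | None   # family → test RPD
    stage3_test_rpd: float | None
    stage3_test_r2: float | None


def hybrid_recovery_run(
    seed: int,
    n: int = 191,
    p: int = 2000,
    run_stage2: bool = True,
    run_stage3: bool = True,
    stage3_budget: int = 20,
) -> HybridRecoveryRun:
    """Run the core pipeline (chain 9 → SPXY → hybrid selection → tuning)
    on one simulated dataset and score it against the planted truth.

    This is the package's parameter-recovery surface: the simulated conditions
    stand in for the unreleased measurement campaign, and recovery of the
    planted informative wavelengths plus held-out RPD quantify whether the
    method does what it claims.
    """
    from .modeling_eval import make_folds as _make_folds
    from .synthetic_mir import selection_recovery
    from .variable_selection import (
        intersect, pls_vip_cv, rfr_importance, select_by_threshold,
        select_top_fraction,
    )

    ds, truth = simulate_dataset(SimConfig(n=n, p=p, seed=seed))
    chain = pp.get_chain(9)
    ds_pre = _preprocessed_dataset(ds, chain)
    split = spxy_split(ds_pre, 0.8)
    cal_rows = np.array([ds.sample_ids.index(s) for s in split.calibration_ids])
    ds_final = _preprocessed_dataset(ds, chain, ref_rows=cal_rows)
    ds_cal = ds_final.subset(split.calibration_ids)
    ds_test = ds_final.subset(split.prediction_ids)

    folds = _make_folds(ds_cal.n_samples, 5, seed=seed)
    vip = pls_vip_cv(ds_cal.X, ds_cal.y, folds)
    gini = rfr_importance(ds_cal.X, ds_cal.y, seed=seed)
    hybrid = intersect(select_by_threshold(vip, 1.0, "PLS-VIP-1.0"),
                       select_top_fraction(gini, 0.30, "RFR-top30%"),
                       "VIP1.0∩RFR30%")
    precision, recall = selection_recovery(hybrid, truth)
    vip08_precision, _ = selection_recovery(
        select_by_threshold(vip, 0.8, "PLS-VIP-0.8"), truth)

    stage2_rpd = None
    if run_stage2:
        rows = stage2_light_tune(hybrid.mask, ds_cal, ds_test, folds, seed=seed)
        stage2_rpd = {r.family: r.test_report.rpd for r in rows
                      if r.test_report is not None}
    s3_rpd = s3_r2 = None
    if run_stage3:
        s3 = stage3_fine_tune(hybrid.mask, ds_cal, ds_test, folds,
                              budget=stage3_budget, seed=seed)
        s3_rpd, s3_r2 = s3.test_report.rpd, s3.test_report.r2
    return HybridRecoveryRun(seed, hybrid.cardinality, precision, recall,
                             vip08_precision, stage2_rpd, s3_rpd, s3_r2)


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def write_reports(result: PipelineResult, out_dir: Path) -> None:
    """Write the per-stage CSV reports and the plain-text trace."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if result.screen_rows is not None:
        pd.DataFrame([
            {"method_id": r.chain.method_id, "method": r.chain.name,
             "n_components": r.n_components,
             "test_r2": r.test_report.r2 if not r.failed else None,
             "rmse": r.test_report.rmse if not r.failed else None,
             "rpd": r.test_report.rpd if not r.failed else None,
             "error": r.error}
            for r in result.screen_rows
        ]).to_csv(out_dir / "preprocessing_screen.csv", index=False)

    pd.DataFrame([
        {"strategy": r.label, "variables": r.n_variables,
         "test_r2": r.test_report.r2 if r.test_report else None,
         "rpd": r.test_report.rpd if r.test_report else None,
         "note": r.note}
        for r in result.stage1_rows
    ]).to_csv(out_dir / "stage1_strategies.csv", index=False)

    sel = result.selected
    grid = result.dataset.spectra.grid
    pd.DataFrame({
        "wavenumber": grid.values,
        "selected": sel.mask.astype(int),
    }).to_csv(out_dir / "selected_wavelengths.csv", index=False)

    if result.stage2_rows is not None:
        pd.DataFrame([
            {"model": r.family,
             "r2_cv": r.cv_report.r2 if r.cv_report else None,
             "rmsecv": r.cv_report.rmse if r.cv_report else None,
             "rpd_cv": r.cv_report.rpd if r.cv_report else None,
             "test_r2": r.test_report.r2 if r.test_report else None,
             "test_rmse": r.test_report.rmse if r.test_report else None,
             "test_rpd": r.test_report.rpd if r.test_report else None,
             "error": r.error}
            for r in result.stage2_rows
        ]).to_csv(out_dir / "stage2_models.csv", index=False)

    if result.stage3 is not None:
        s3 = result.stage3
        pd.DataFrame([
            {"dataset": "calibration_cv", "r2": s3.cv_report.r2,
             "rmse": s3.cv_report.rmse, "rpd": s3.cv_report.rpd},
            {"dataset": "prediction", "r2": s3.test_report.r2,
             "rmse": s3.test_report.rmse, "rpd": s3.test_report.rpd},
        ]).to_csv(out_dir / "final_model.csv", index=False)

    with open(out_dir / "trace.log", "w") as fh:
        fh.write("\n".join(result.trace) + "\n")
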