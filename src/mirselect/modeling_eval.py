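"""Regression metrics (R², RMSE, RPD, Williams categories), cross-validation
folds, the four-model suite (PLS, random forest, RBF-SVR, gradient-boosted
trees), and the three-stage hyperparameter tuning protocol.

Stage 1 compares variable-selection strategies with a frozen booster so the
comparison reflects the subsets, not the tuning. Stage 2 gives each model
family an equal, light tuning budget on the winning subset. Stage 3 fine-tunes
the boosted-tree model by seeded random search on the calibration folds only;
the prediction set is evaluated exactly once, after the search.

CV metrics are computed on pooled out-of-fold predictions (a single
well-defined statistic at small n) rather than averaged per-fold scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = [
    "FoldPlan",
    "EvalReport",
    "ModelSpec",
    "make_folds",
    "evaluate",
    "williams_category",
    "percent_improvement",
    "overfit_gap",
    "fit_pls_cv",
    "stage1_compare",
    "stage2_light_tune",
    "stage3_fine_tune",
    "STAGE1_FIXED_PARAMS",
    "STAGE2_GRIDS",
    "STAGE3_RANGES",
]

MODEL_FAMILIES = ("pls", "rfr", "svr_rbf", "gbt")

#: frozen booster parameters for the stage-1 strategy comparison
STAGE1_FIXED_PARAMS: Mapping[str, float | int] = {
    "max_depth": 3,
    "learning_rate": 0.1,
    "n_estimators": 300,
}

#: stage-2 light-tuning search spaces, one per model family
STAGE2_GRIDS: Mapping[str, Mapping[str, Sequence]] = {
    "pls": {"n_components": tuple(range(5, 16))},
    "rfr": {"max_depth": (4, 6, 8, 10), "min_samples_leaf": (2, 3, 5)},
    "svr_rbf": {"C": (1.0, 10.0, 100.0), "gamma": (1e-3, 1e-2, 1e-1)},
    "gbt": {"max_depth": (3, 4, 5), "learning_rate": (0.05, 0.1)},
}

#: stage-3 fine-tuning ranges for the boosted-tree model
STAGE3_RANGES: Mapping[str, tuple[float, float]] = {
    "n_estimators": (50, 500),
    "max_depth": (2, 6),
    "learning_rate": (0.01, 0.3),
    "subsample": (0.6, 1.0),
    "colsample_bytree": (0.6, 1.0),
    "reg_alpha": (0.0, 1.0),
    "reg_lambda": (0.0, 2.0),
}

#: early-stopping patience (boosting rounds on the held-out fold) in stage 3
EARLY_STOPPING_PATIENCE = 20

#: number of trees used when stage 2 tunes only depth/learning-rate
STAGE2_GBT_N_ESTIMATORS = 300
STAGE2_RFR_N_ESTIMATORS = 300


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """k disjoint validation-index sets partitioning the calibration rows."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        flat = [i for fold in self.folds for i in fold]
        n = len(flat)
        if sorted(flat) != list(range(n)):
            raise ValueError("folds must partition 0..n-1 exactly")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def n(self) -> int:
        return sum(len(f) for f in self.folds)

    def split(self):
        """Yield (train_idx, val_idx) pairs as integer arrays."""
        all_idx = np.arange(self.n)
        for fold in self.folds:
            val = np.asarray(fold, dtype=int)
            mask = np.ones(self.n, dtype=bool)
            mask[val] = False
            yield all_idx[mask], val


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded shuffle then near-equal contiguous chunking into k folds."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, k)
    return FoldPlan(tuple(tuple(int(i) for i in c) for c in chunks), seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """R², RMSE and RPD for a (y, ŷ) pair, with the Williams category.

    ``sd_ref`` is the (n−1)-denominator standard deviation of the reference
    values of the evaluated set; RPD = sd_ref / RMSE.
    """

    r2: float
    rmse: float
    rpd: float
    sd_ref: float
    williams: str
    n: int
    tag: str
    rpd_infinite: bool = False


def evaluate(
    y: np.ndarray,
    y_hat: np.ndarray,
    sd_ref_source: np.ndarray | None = None,
    tag: str = "test",
) -> EvalReport:
    """Score predictions: R² (1 − SSE/SST), RMSE, RPD = SD_ref/RMSE."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("need equal-length y and y_hat with n >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference values are constant; R² undefined")
    sse = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - sse / sst
    rmse = math.sqrt(sse / y.size)
    ref = y if sd_ref_source is None else np.asarray(sd_ref_source, dtype=float)
    sd_ref = float(np.std(ref, ddof=1))
    if rmse == 0.0:
        return EvalReport(r2, rmse, math.inf, sd_ref, williams_category(math.inf),
                          y.size, tag, rpd_infinite=True)
    rpd = sd_ref / rmse
    return EvalReport(r2, rmse, rpd, sd_ref, williams_category(rpd), y.size, tag)


def williams_category(rpd: float) -> str:
    """Map an RPD value to its Williams interpretation band."""
    if rpd < 0:
        raise ValueError("RPD cannot be negative")
    if rpd < 1.5:
        return "unreliable"
    if rpd < 2.0:
        return "rough screening"
    if rpd < 2.5:
        return "approximate quantification"
    if rpd < 3.0:
        return "good prediction"
    return "excellent prediction"


def percent_improvement(new: float, base: float) -> float:
    """Relative change 100·(new − base)/base, reported to 1 decimal."""
    if base == 0:
        raise ValueError("baseline is zero; relative improvement undefined")
    return round(100.0 * (new - base) / base, 1)


def overfit_gap(r2_cal: float, r2_test: float) -> float:
    """Calibration-minus-prediction R² gap, to 4 decimals."""
    return round(r2_cal - r2_test, 4)


# ---------------------------------------------------------------------------
# Model specs and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A model family plus concrete hyperparameters and a seed."""

    family: str
    params: Mapping[str, float | int]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    def build(self):
        """Instantiate an unfitted scikit-learn style estimator."""
        p = dict(self.params)
        if self.family == "pls":
            return PLSRegression(n_components=int(p["n_components"]), scale=False)
        if self.family == "rfr":
            return RandomForestRegressor(
                n_estimators=int(p.get("n_estimators", STAGE2_RFR_N_ESTIMATORS)),
                max_depth=p.get("max_depth"),
                min_samples_leaf=int(p.get("min_samples_leaf", 1)),
                random_state=self.seed,
                n_jobs=1,
            )
        if self.family == "svr_rbf":
            # kernel methods need per-variable scaling; the scaler is part of
            # the pipeline so it is always fitted on training rows only
            return Pipeline([
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", C=p["C"], gamma=p["gamma"])),
            ])
        if self.family == "gbt":
            return XGBRegressor(
                n_estimators=int(p.get("n_estimators", STAGE2_GBT_N_ESTIMATORS)),
                max_depth=int(p.get("max_depth", 3)),
                learning_rate=float(p.get("learning_rate", 0.1)),
                subsample=float(p.get("subsample", 1.0)),
                colsample_bytree=float(p.get("colsample_bytree", 1.0)),
                reg_alpha=float(p.get("reg_alpha", 0.0)),
                reg_lambda=float(p.get("reg_lambda", 1.0)),
                random_state=self.seed,
                n_jobs=1,
                verbosity=0,
            )
        raise AssertionError(self.family)


def _oof_predictions(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                     folds: FoldPlan) -> np.ndarray:
    """Pooled out-of-fold predictions for a spec under a shared fold plan."""
    oof = np.empty(folds.n, dtype=float)
    for train, val in folds.split():
        model = spec.build()
        model.fit(X[train], y[train])
        oof[val] = np.asarray(model.predict(X[val])).ravel()
    return oof


@dataclass(frozen=True)
class PlsCvFit:
    """PLS refit on the full calibration set at the CV-chosen component count."""

    model: PLSRegression
    n_components: int
    rmsecv: float
    oof_predictions: np.ndarray
    rmsecv_by_components: Mapping[int, float]


def fit_pls_cv(X: np.ndarray, y: np.ndarray, folds: FoldPlan,
               max_components: int = 15) -> PlsCvFit:
    """Choose the PLS latent-variable count by k-fold RMSECV over 1..max.

    The candidate range is capped by the training dimensions of the smallest
    fold; ties in RMSECV go to the smaller component count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    min_train = min(len(train) for train, _ in folds.split())
    cap = max(1, min(max_components, X.shape[1], min_train - 1))
    best = None
    rmse_by_a: dict[int, float] = {}
    oof_best = None
    for a in range(1, cap + 1):
        spec = ModelSpec("pls", {"n_components": a})
        oof = _oof_predictions(spec, X, y, folds)
        rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
        rmse_by_a[a] = rmse
        if best is None or rmse < best[1]:
            best = (a, rmse)
            oof_best = oof
    a_best, rmsecv = best
    model = PLSRegression(n_components=a_best, scale=False)
    model.fit(X, y)
    return PlsCvFit(model, a_best, rmsecv, oof_best, rmse_by_a)


# ---------------------------------------------------------------------------
# Stage 1: strategy comparison with a frozen booster
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage1Row:
    """One strategy's frozen-booster performance on the prediction set."""

    label: str
    n_variables: int
    test_report: EvalReport | None
    booster_params: Mapping[str, float | int]
    note: str | None = None


def stage1_compare(
    strategies: Sequence,
    ds_cal,
    ds_test,
    seed: int = 0,
) -> list[Stage1Row]:
    """Rank selection strategies with identical fixed booster parameters.

    ``strategies`` is a sequence of SelectionResult-like objects (``mask`` and
    ``label`` attributes). Empty selections are reported as NA rows rather
    than errors. Rows are sorted by test R² descending, NA rows last.
    """
    rows: list[Stage1Row] = []
    for sel in strategies:
        mask = np.asarray(sel.mask, dtype=bool)
        if mask.sum() == 0:
            rows.append(Stage1Row(sel.label, 0, None, dict(STAGE1_FIXED_PARAMS),
                                  note="empty selection"))
            continue
        spec = ModelSpec("gbt", STAGE1_FIXED_PARAMS, seed=seed)
        model = spec.build()
        model.fit(ds_cal.X[:, mask], ds_cal.y)
        y_hat = np.asarray(model.predict(ds_test.X[:, mask])).ravel()
        report = evaluate(ds_test.y, y_hat, tag="test")
        rows.append(Stage1Row(sel.label, int(mask.sum()), report,
                              dict(STAGE1_FIXED_PARAMS)))
    rows.sort(key=lambda r: (-(r.test_report.r2 if r.test_report else -math.inf)))
    return rows


# ---------------------------------------------------------------------------
# Stage 2: equal-budget light tuning across the four families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage2Row:
    family: str
    spec: ModelSpec | None
    cv_report: EvalReport | None
    test_report: EvalReport | None
    error: str | None = None


def _stage2_candidates(family: str, n_cal: int, p_sel: int,
                       seed: int) -> list[ModelSpec]:
    grid = STAGE2_GRIDS[family]
    if family == "pls":
        cap = max(1, min(n_cal - 1, p_sel))
        comps = [a for a in grid["n_components"] if a <= cap] or [cap]
        return [ModelSpec("pls", {"n_components": a}) for a in comps]
    if family == "rfr":
        return [
            ModelSpec("rfr", {"max_depth": d, "min_samples_leaf": leaf,
                              "n_estimators": STAGE2_RFR_N_ESTIMATORS}, seed=seed)
            for d in grid["max_depth"] for leaf in grid["min_samples_leaf"]
        ]
    if family == "svr_rbf":
        return [ModelSpec("svr_rbf", {"C": c, "gamma": g})
                for c in grid["C"] for g in grid["gamma"]]
    if family == "gbt":
        # the 3×2 space is small enough to enumerate outright
        return [
            ModelSpec("gbt", {"max_depth": d, "learning_rate": lr,
                              "n_estimators": STAGE2_GBT_N_ESTIMATORS}, seed=seed)
            for d in grid["max_depth"] for lr in grid["learning_rate"]
        ]
    raise AssertionError(family)


def stage2_light_tune(
    mask: np.ndarray,
    ds_cal,
    ds_test,
    folds: FoldPlan,
    seed: int = 0,
    families: Sequence[str] = MODEL_FAMILIES,
) -> list[Stage2Row]:
    """Light per-family tuning of the selected subset under a shared fold plan.

    Each family's grid is searched by pooled-out-of-fold RMSECV; the best spec
    is refit on the full calibration set and evaluated once on the test set.
    """
    mask = np.asarray(mask, dtype=bool)
    Xc, yc = ds_cal.X[:, mask], ds_cal.y
    Xt, yt = ds_test.X[:, mask], ds_test.y
    rows: list[Stage2Row] = []
    for family in families:
        try:
            best = None
            for spec in _stage2_candidates(family, Xc.shape[0], Xc.shape[1], seed):
                oof = _oof_predictions(spec, Xc, yc, folds)
                rmse = float(np.sqrt(np.mean((yc - oof) ** 2)))
                if best is None or rmse < best[1]:
                    best = (spec, rmse, oof)
            spec, _, oof = best
            cv_report = evaluate(yc, oof, tag="cv")
            model = spec.build()
            model.fit(Xc, yc)
            test_report = evaluate(yt, np.asarray(model.predict(Xt)).ravel(),
                                   tag="test")
            rows.append(Stage2Row(family, spec, cv_report, test_report))
        except ValueError as exc:
            rows.append(Stage2Row(family, None, None, None, error=str(exc)))
    return rows


# ---------------------------------------------------------------------------
# Stage 3: seeded random search fine-tuning of the boosted-tree model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage3Result:
    spec: ModelSpec
    cv_report: EvalReport
    test_report: EvalReport
    rmsecv: float
    n_specs_tried: int
    n_test_evaluations: int
    search_trace: tuple[tuple[ModelSpec, float], ...] = field(repr=False)


def sample_stage3_spec(rng: np.random.Generator, seed: int) -> ModelSpec:
    """Draw one boosted-tree spec uniformly from the fine-tuning ranges."""
    r = STAGE3_RANGES
    params = {
        "n_estimators": int(rng.integers(r["n_estimators"][0],
                                         r["n_estimators"][1] + 1)),
        "max_depth": int(rng.integers(r["max_depth"][0], r["max_depth"][1] + 1)),
        "learning_rate": float(rng.uniform(*r["learning_rate"])),
        "subsample": float(rng.uniform(*r["subsample"])),
        "colsample_bytree": float(rng.uniform(*r["colsample_bytree"])),
        "reg_alpha": float(rng.uniform(*r["reg_alpha"])),
        "reg_lambda": float(rng.uniform(*r["reg_lambda"])),
    }
    return ModelSpec("gbt", params, seed=seed)


def _gbt_cv_with_early_stopping(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                                folds: FoldPlan) -> tuple[np.ndarray, list[int]]:
    """Pooled OOF predictions with per-fold early stopping on the held-out fold."""
    oof = np.empty(folds.n, dtype=float)
    best_rounds: list[int] = []
    for train, val in folds.split():
        model = XGBRegressor(
            n_estimators=int(spec.params["n_estimators"]),
            max_depth=int(spec.params["max_depth"]),
            learning_rate=float(spec.params["learning_rate"]),
            subsample=float(spec.params["subsample"]),
            colsample_bytree=float(spec.params["colsample_bytree"]),
            reg_alpha=float(spec.params["reg_alpha"]),
            reg_lambda=float(spec.params["reg_lambda"]),
            random_state=spec.seed,
            n_jobs=1,
            verbosity=0,
            early_stopping_rounds=EARLY_STOPPING_PATIENCE,
            eval_metric="rmse",
        )
        model.fit(X[train], y[train], eval_set=[(X[val], y[val])], verbose=False)
        oof[val] = np.asarray(model.predict(X[val])).ravel()
        best_it = getattr(model, "best_iteration", None)
        best_rounds.append(int(best_it) + 1 if best_it is not None
                           else int(spec.params["n_estimators"]))
    return oof, best_rounds


def stage3_fine_tune(
    mask: np.ndarray,
    ds_cal,
    ds_test,
    folds: FoldPlan,
    budget: int = 60,
    seed: int = 0,
) -> Stage3Result:
    """Seeded random search over the fine-tuning ranges, CV on calibration only.

    Each candidate is scored by pooled out-of-fold RMSECV with early stopping
    (patience 20 rounds) against the held-out fold. The CV-best spec — its
    tree count replaced by the mean early-stopped round count — is refit on the
    full calibration set, and the prediction set is evaluated exactly once,
    after the search. The returned trace records every candidate and its
    RMSECV, and ``n_test_evaluations`` asserts the leakage contract.
    """
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("cannot tune on an empty variable selection")
    Xc, yc = ds_cal.X[:, mask], ds_cal.y
    rng = np.random.default_rng(seed)
    trace: list[tuple[ModelSpec, float]] = []
    best: tuple[ModelSpec, float, np.ndarray, list[int]] | None = None
    for _ in range(budget):
        spec = sample_stage3_spec(rng, seed=seed)
        oof, rounds = _gbt_cv_with_early_stopping(spec, Xc, yc, folds)
        rmse = float(np.sqrt(np.mean((yc - oof) ** 2)))
        trace.append((spec, rmse))
        if best is None or rmse < best[1]:
            best = (spec, rmse, oof, rounds)
    spec, rmsecv, oof, rounds = best
    final_params = dict(spec.params)
    final_params["n_estimators"] = max(1, int(round(float(np.mean(rounds)))))
    final_spec = ModelSpec("gbt", final_params, seed=seed)
    cv_report = evaluate(yc, oof, tag="cv")
    model = final_spec.build()
    model.fit(Xc, yc)
    # the single, post-selection touch of the prediction set
    yt_hat = np.asarray(model.predict(ds_test.X[:, mask])).ravel()
    test_report = evaluate(ds_test.y, yt_hat, tag="test")
    return Stage3Result(
        spec=final_spec,
        cv_report=cv_report,
        test_report=test_report,
        rmsecv=rmsecv,
        n_specs_tried=len(trace),
        n_test_evaluations=1,
        search_trace=tuple(trace),
    )
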