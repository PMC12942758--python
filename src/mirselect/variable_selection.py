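"""Wavelength selection: PLS-VIP and random-forest importance engines, the
threshold/top-fraction/intersection strategy algebra, the six-strategy
candidate pool, and the CARS (competitive adaptive reweighted sampling)
baseline.

The hybrid strategy intersects a linear criterion (VIP ≥ threshold from a PLS
model) with a nonlinear one (top fraction of normalized Gini importance from
a random forest), retaining only wavelengths validated from both modeling
perspectives — a dual-lock filter against spurious variables in the p >> n
regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

from .modeling_eval import FoldPlan, fit_pls_cv, make_folds

__all__ = [
    "ImportanceProfile",
    "SelectionResult",
    "CarsTrace",
    "StrategyPoolConfig",
    "pls_vip",
    "rfr_importance",
    "select_by_threshold",
    "select_top_fraction",
    "intersect",
    "build_strategy_pool",
    "cars",
    "reduction_percent",
]

#: default forest used for Gini importance: many shallow-correlation-tolerant
#: trees with a reduced feature fraction per split, which spreads importance
#: across correlated spectral neighbourhoods instead of piling it on a single
#: representative wavelength
DEFAULT_FOREST_PARAMS: Mapping[str, object] = {
    "n_estimators": 500,
    "max_features": 0.3,
    "min_samples_leaf": 1,
}

#: Monte-Carlo row-subsample ratio per CARS run
CARS_ROW_SUBSAMPLE = 0.8
#: component cap for the PLS models inside CARS
CARS_MAX_COMPONENTS = 10


@dataclass(frozen=True)
class ImportanceProfile:
    """Per-wavelength importance scores from one engine (``vip`` or ``gini``)."""

    scores: np.ndarray
    method: str
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "metadata", dict(self.metadata))
        if scores.ndim != 1:
            raise ValueError("scores must be a 1-D vector")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores contain non-finite values")
        if np.any(scores < 0):
            raise ValueError("importance scores must be non-negative")
        if self.method not in ("vip", "gini"):
            raise ValueError(f"unknown importance method {self.method!r}")

    @property
    def p(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class SelectionResult:
    """A boolean wavelength mask plus bookkeeping for one strategy."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 1:
            raise ValueError("mask must be 1-D")

    @property
    def p(self) -> int:
        return int(self.mask.size)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def cardinality(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.cardinality == 0

    @property
    def reduction(self) -> float:
        return reduction_percent(self.p, self.cardinality)


def reduction_percent(p_total: int, p_selected: int) -> float:
    """Dimensionality reduction 100·(1 − selected/total), to 1 decimal."""
    if p_total <= 0:
        raise ValueError("p_total must be positive")
    if not 0 <= p_selected <= p_total:
        raise ValueError("p_selected must lie in [0, p_total]")
    return round(100.0 * (1.0 - p_selected / p_total), 1)


# ---------------------------------------------------------------------------
# Importance engines
# ---------------------------------------------------------------------------

def pls_vip(X_cal: np.ndarray, y_cal: np.ndarray,
            n_components: int) -> ImportanceProfile:
    """Variable importance in projection from a PLS fit with A components.

    VIP_j = sqrt( p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a ), where SS_a is the
    y sum-of-squares explained by component a and w_a its X-weight vector.
    The mean squared VIP is exactly 1 (Σ_j VIP_j² = p).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("reference values have zero variance")
    n, p = X.shape
    A = int(n_components)
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, min(n-1, p)], got {A}")
    model = PLSRegression(n_components=A, scale=False)
    model.fit(X, y)
    W = model.x_weights_            # p × A
    T = model.x_scores_             # n × A
    Q = model.y_loadings_.ravel()   # A
    ss = (Q**2) * np.sum(T**2, axis=0)          # explained y sum of squares
    w_norm = W / np.linalg.norm(W, axis=0)      # unit-norm weight vectors
    vip = np.sqrt(p * (w_norm**2 @ ss) / ss.sum())
    return ImportanceProfile(vip, "vip", {"n_components": A})


def pls_vip_cv(X_cal: np.ndarray, y_cal: np.ndarray, folds: FoldPlan,
               max_components: int = 15) -> ImportanceProfile:
    """VIP with the latent-variable count chosen by k-fold RMSECV."""
    fit = fit_pls_cv(X_cal, y_cal, folds, max_components=max_components)
    prof = pls_vip(X_cal, y_cal, fit.n_components)
    meta = dict(prof.metadata)
    meta["rmsecv"] = fit.rmsecv
    return ImportanceProfile(prof.scores, "vip", meta)


def rfr_importance(X_cal: np.ndarray, y_cal: np.ndarray,
                   forest_params: Mapping[str, object] | None = None,
                   seed: int = 0) -> ImportanceProfile:
    """Normalized Gini (mean decrease in impurity) importance from a forest."""
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to fit a forest")
    params = dict(DEFAULT_FOREST_PARAMS)
    if forest_params:
        params.update(forest_params)
    forest = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    forest.fit(X, y)
    scores = forest.feature_importances_.astype(float)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    meta = {"seed": seed, **params}
    return ImportanceProfile(scores, "gini", meta)


# ---------------------------------------------------------------------------
# Strategy algebra
# ---------------------------------------------------------------------------

def select_by_threshold(prof: ImportanceProfile, tau: float,
                        label: str | None = None) -> SelectionResult:
    """Keep wavelengths with score ≥ tau (inclusive)."""
    mask = prof.scores >= tau
    return SelectionResult(mask, label or f"{prof.method.upper()}>={tau:g}")


def select_top_fraction(prof: ImportanceProfile, q: float,
                        label: str | None = None) -> SelectionResult:
    """Keep the floor(q·p) highest-scoring wavelengths.

    Every selected score is ≥ every unselected score; ties at the cut are
    broken in favour of the lower wavelength index.
    """
    if not 0 < q <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(math.floor(q * prof.p))
    if k == 0:
        raise ValueError(f"floor({q}·{prof.p}) = 0 wavelengths")
    # stable sort on negated scores: equal scores keep ascending index order
    order = np.argsort(-prof.scores, kind="stable")
    mask = np.zeros(prof.p, dtype=bool)
    mask[order[:k]] = True
    return SelectionResult(mask, label or f"{prof.method.upper()}-top{q:.0%}")


def intersect(a: SelectionResult, b: SelectionResult,
              label: str | None = None) -> SelectionResult:
    """Wavelengths retained by both strategies (the dual-lock filter)."""
    if a.p != b.p:
        raise ValueError("selections cover different numbers of wavelengths")
    return SelectionResult(a.mask & b.mask, label or f"{a.label}∩{b.label}")


# ---------------------------------------------------------------------------
# Strategy pool
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyPoolConfig:
    """Knobs for the six-strategy candidate pool."""

    vip_max_components: int = 15
    cv_k: int = 5
    cv_seed: int = 0
    forest_params: Mapping[str, object] | None = None
    forest_seed: int = 0
    cars_iterations: int = 50
    cars_mc_runs: int = 10
    cars_seed: int = 0


#: the canonical strategy labels, in comparison-table order
STRATEGY_LABELS = (
    "VIP1.0∩RFR30%",
    "RFR-top10%",
    "VIP-1.2∩RFR-20%",
    "PLS-VIP-1.2",
    "PLS-VIP-0.8",
    "CARS",
)


def build_strategy_pool(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    config: StrategyPoolConfig = StrategyPoolConfig(),
) -> tuple[list[SelectionResult], dict[str, ImportanceProfile]]:
    """Build the six labeled candidate strategies from shared importance profiles.

    The VIP and Gini profiles are computed once and shared across strategies;
    CARS runs its own iterative search. Empty selections are legal (flagged
    via ``is_empty``), never errors, so downstream comparisons always see six
    rows. Returns (pool, profiles).
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    folds = make_folds(X.shape[0], config.cv_k, seed=config.cv_seed)
    vip = pls_vip_cv(X, y, folds, max_components=config.vip_max_components)
    gini = rfr_importance(X, y, config.forest_params, seed=config.forest_seed)

    vip10 = select_by_threshold(vip, 1.0, "PLS-VIP-1.0")
    vip12 = select_by_threshold(vip, 1.2, "PLS-VIP-1.2")
    vip08 = select_by_threshold(vip, 0.8, "PLS-VIP-0.8")
    rfr30 = select_top_fraction(gini, 0.30, "RFR-top30%")
    rfr20 = select_top_fraction(gini, 0.20, "RFR-top20%")
    rfr10 = select_top_fraction(gini, 0.10, "RFR-top10%")

    _, cars_sel = cars(X, y, n_iterations=config.cars_iterations,
                       n_mc_runs=config.cars_mc_runs, folds=folds,
                       seed=config.cars_seed)

    pool = [
        intersect(vip10, rfr30, "VIP1.0∩RFR30%"),
        SelectionResult(rfr10.mask, "RFR-top10%"),
        intersect(vip12, rfr20, "VIP-1.2∩RFR-20%"),
        SelectionResult(vip12.mask, "PLS-VIP-1.2"),
        SelectionResult(vip08.mask, "PLS-VIP-0.8"),
        SelectionResult(cars_sel.mask, "CARS"),
    ]
    return pool, {"vip": vip, "gini": gini}


# ---------------------------------------------------------------------------
# CARS baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarsIteration:
    index: int  # 1-based
    retained: tuple[int, ...]
    rmsecv: float

    @property
    def retained_count(self) -> int:
        return len(self.retained)


@dataclass(frozen=True)
class CarsTrace:
    """Per-iteration record of a CARS run plus the EDF parameters."""

    iterations: tuple[CarsIteration, ...]
    chosen_iteration: int  # 1-based index into `iterations`
    edf_a: float
    edf_k: float
    truncated: bool = False


def cars_retention_ratio(i: int, p: int, n_iterations: int) -> float:
    """Exponentially decreasing forced-retention ratio r_i = a·e^(−k·i).

    With a = (p/2)^(1/(N−1)) and k = ln(p/2)/(N−1): r_1 = 1 (keep everything)
    and r_N = 2/p (keep two variables).
    """
    if n_iterations < 2:
        raise ValueError("CARS needs at least 2 iterations")
    a = (p / 2.0) ** (1.0 / (n_iterations - 1))
    k = math.log(p / 2.0) / (n_iterations - 1)
    return a * math.exp(-k * i)


def cars(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    n_iterations: int = 50,
    n_mc_runs: int = 10,
    folds: FoldPlan | None = None,
    seed: int = 0,
) -> tuple[CarsTrace, SelectionResult]:
    """Competitive adaptive reweighted sampling.

    Each iteration i:

    1. fit PLS on ``n_mc_runs`` Monte-Carlo row subsamples (80% of rows) of
       the currently retained variables; average the absolute regression
       coefficients into per-variable weights;
    2. enforced elimination — keep the round(r_i·p) largest-weight variables,
       with r_i following the exponentially decreasing function;
    3. adaptive reweighted sampling — draw that many variables with
       replacement, probability proportional to weight; survivors are the
       distinct draws;
    4. record the 5-fold RMSECV of a CV-tuned PLS model on the survivors.

    The returned subset is the iteration minimizing RMSECV. Fully determined
    by the seed; stops early (truncated trace) if fewer than 2 variables
    survive.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    if n_iterations < 2:
        raise ValueError("CARS needs at least 2 iterations")
    if folds is None:
        folds = make_folds(n, 5, seed=seed)
    rng = np.random.default_rng(seed)
    a_edf = (p / 2.0) ** (1.0 / (n_iterations - 1))
    k_edf = math.log(p / 2.0) / (n_iterations - 1)

    retained = np.arange(p)
    records: list[CarsIteration] = []
    truncated = False
    n_rows = max(2, int(math.floor(CARS_ROW_SUBSAMPLE * n)))
    for i in range(1, n_iterations + 1):
        weights = np.zeros(retained.size)
        for _ in range(n_mc_runs):
            rows = rng.choice(n, size=n_rows, replace=False)
            a_fit = max(1, min(CARS_MAX_COMPONENTS, retained.size, n_rows - 1))
            model = PLSRegression(n_components=a_fit, scale=False)
            model.fit(X[np.ix_(rows, retained)], y[rows])
            weights += np.abs(model.coef_).ravel()
        weights /= n_mc_runs

        r_i = a_edf * math.exp(-k_edf * i)
        keep = min(max(2, int(round(r_i * p))), retained.size)
        order = np.argsort(-weights, kind="stable")
        top = np.sort(order[:keep])  # positions within `retained`
        survivors = retained[top]
        w_surv = weights[top]

        # adaptive reweighted sampling among survivors
        total = w_surv.sum()
        prob = w_surv / total if total > 0 else np.full(keep, 1.0 / keep)
        draws = rng.choice(survivors, size=keep, replace=True, p=prob)
        retained = np.unique(draws)
        if retained.size < 2:
            truncated = True
            break

        fit = fit_pls_cv(X[:, retained], y, folds,
                         max_components=CARS_MAX_COMPONENTS)
        records.append(CarsIteration(i, tuple(int(v) for v in retained),
                                     fit.rmsecv))

    if not records:
        raise ValueError("CARS eliminated all variables before the first record")
    rmse = np.array([r.rmsecv for r in records])
    chosen = int(np.argmin(rmse))  # first minimum
    best = records[chosen]
    mask = np.zeros(p, dtype=bool)
    mask[list(best.retained)] = True
    trace = CarsTrace(tuple(records), chosen + 1, a_edf, k_edf, truncated)
    return trace, SelectionResult(mask, "CARS")
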