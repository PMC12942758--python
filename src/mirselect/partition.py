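"""Calibration/prediction partitioning: SPXY and Kennard–Stone.

Both algorithms are deterministic maximin selectors: they seed the
calibration set with the two mutually most-distant samples and then
repeatedly add the sample whose minimum distance to the already-selected set
is largest. Kennard–Stone measures Euclidean distance in spectral (X) space
only; SPXY adds a normalized distance in reference-value (y) space,

    d_xy(p, q) = d_x(p, q) / max d_x  +  d_y(p, q) / max d_y,

so the calibration set spans both spectral and chemical variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .modeling_eval import EvalReport, FoldPlan, evaluate, fit_pls_cv, make_folds
from .spectral_data import Dataset

__all__ = [
    "SplitResult",
    "joint_distance_matrix",
    "joint_distance",
    "spxy_split",
    "kennard_stone_split",
    "compare_partitioners",
]


@dataclass(frozen=True)
class SplitResult:
    """A deterministic calibration/prediction split of a Dataset's ids."""

    calibration_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    method: str  # "spxy" | "ks"
    fraction: float

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.prediction_ids):
            raise ValueError("calibration and prediction ids overlap")

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_ids)


def _x_distance_matrix(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, dtype=float), metric="euclidean"))


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs SPXY distance: normalized X-distance plus normalized y-distance.

    Each term is divided by its maximum over the candidate pool, so entries
    lie in [0, 2] and the pair maximizing both terms attains exactly 2.
    """
    dx = _x_distance_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    dy = np.abs(y[:, None] - y[None, :])
    dx_max = dx.max()
    dy_max = dy.max()
    if dx_max == 0:
        raise ValueError("all spectra identical: X-distance normalizer is zero")
    if dy_max == 0:
        raise ValueError("all reference values identical: y-distance normalizer is zero")
    return dx / dx_max + dy / dy_max


def joint_distance(p_idx: int, q_idx: int, X: np.ndarray, y: np.ndarray) -> float:
    """SPXY distance between two samples, normalized over the whole pool."""
    return float(joint_distance_matrix(X, y)[p_idx, q_idx])


def _maximin_select(D: np.ndarray, n_select: int) -> list[int]:
    """Classical maximin accretion on a distance matrix.

    Seeds with the most-distant pair, then repeatedly adds the candidate whose
    minimum distance to the selected set is largest. All argmax ties are broken
    by the lowest sample index, making the procedure fully deterministic.
    """
    n = D.shape[0]
    # seed: lexicographically first pair attaining the max distance
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest-index) max
    selected = [int(iu[0][best]), int(iu[1][best])]
    remaining = [i for i in range(n) if i not in selected]
    min_dist = np.minimum(D[remaining][:, selected[0]], D[remaining][:, selected[1]])
    while len(selected) < n_select:
        pick = int(np.argmax(min_dist))
        chosen = remaining.pop(pick)
        selected.append(chosen)
        min_dist = np.delete(min_dist, pick)
        if remaining:
            min_dist = np.minimum(min_dist, D[remaining, chosen])
    return selected


def _split(ds: Dataset, fraction: float, D: np.ndarray, method: str) -> SplitResult:
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_cal = int(np.floor(fraction * n))
    if n_cal < 2:
        raise ValueError(f"calibration size floor({fraction}·{n}) < 2")
    chosen = set(_maximin_select(D, n_cal))
    ids = ds.sample_ids
    cal = tuple(ids[i] for i in sorted(chosen))
    pred = tuple(ids[i] for i in range(n) if i not in chosen)
    return SplitResult(cal, pred, method, fraction)


def spxy_split(ds: Dataset, fraction: float = 0.8) -> SplitResult:
    """Deterministic SPXY split on joint spectral/reference distances."""
    return _split(ds, fraction, joint_distance_matrix(ds.X, ds.y), "spxy")


def kennard_stone_split(ds: Dataset, fraction: float = 0.8) -> SplitResult:
    """Deterministic Kennard–Stone split on spectral distances only."""
    D = _x_distance_matrix(ds.X)
    if D.max() == 0:
        raise ValueError("all spectra identical: distance normalizer is zero")
    return _split(ds, fraction, D, "ks")


@dataclass(frozen=True)
class PartitionComparisonRow:
    method: str
    split: SplitResult
    test_report: EvalReport
    rpd_sd_over_repeats: float


def compare_partitioners(
    ds: Dataset,
    fraction: float = 0.8,
    cv_k: int = 5,
    cv_seed: int = 0,
    max_components: int = 15,
    n_repeats: int = 3,
    methods: Sequence[str] = ("spxy", "ks"),
    reseed_cv: bool = False,
) -> list[PartitionComparisonRow]:
    """Compare SPXY and Kennard–Stone with a CV-tuned PLS model.

    For each method: split, choose the PLS component count by k-fold RMSECV on
    the calibration set, evaluate on the prediction set. Both splitters and
    the default fold plan are deterministic, so the reported RPD standard
    deviation over repeats is zero unless ``reseed_cv`` is set, in which case
    repeats reseed the fold plan and the sd measures model-side variation
    only.
    """
    rows = []
    splitters = {"spxy": spxy_split, "ks": kennard_stone_split}
    for method in methods:
        split = splitters[method](ds, fraction)
        rpds = []
        last_report = None
        for rep in range(n_repeats):
            folds = make_folds(split.n_calibration, cv_k,
                               seed=cv_seed + rep if reseed_cv else cv_seed)
            ds_cal = ds.subset(split.calibration_ids)
            ds_test = ds.subset(split.prediction_ids)
            fit = fit_pls_cv(ds_cal.X, ds_cal.y, folds, max_components)
            y_hat = np.asarray(fit.model.predict(ds_test.X)).ravel()
            last_report = evaluate(ds_test.y, y_hat, tag="test")
            rpds.append(last_report.rpd)
        sd = float(np.std(rpds, ddof=1)) if len(rpds) > 1 else 0.0
        rows.append(PartitionComparisonRow(method, split, last_report, sd))
    return rows
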