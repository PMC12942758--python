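"""Spectral preprocessing: SNV, MSC, Savitzky–Golay, detrending, and the
ten-chain catalogue screened by PLS cross-validation.

Powdered-sample ATR-MIR spectra carry multiplicative scatter (particle-size
effects), additive baseline drift, and high-frequency noise on top of the
chemical absorbance signal. Each catalogue chain combines scatter correction
(SNV or MSC), local polynomial smoothing/differentiation (Savitzky–Golay), or
polynomial detrending. Chains are applied left-to-right, scatter correction
before derivative, matching their names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .modeling_eval import EvalReport, FoldPlan, evaluate, fit_pls_cv
from .spectral_data import Dataset, WavenumberGrid

__all__ = [
    "MscReference",
    "PreprocChain",
    "CHAIN_CATALOGUE",
    "snv",
    "msc_fit",
    "msc_apply",
    "savitzky_golay",
    "detrend",
    "apply_chain",
    "screen_preprocessing",
]

# SG settings used throughout the catalogue: window 11 points, quadratic.
SG_WINDOW = 11
SG_POLYORDER = 2
#: default polynomial degree for the detrending chain (quadratic baseline)
DETREND_DEGREE = 2


@dataclass(frozen=True)
class MscReference:
    """Mean calibration spectrum used as the MSC regression reference."""

    spectrum: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.spectrum, dtype=float)
        object.__setattr__(self, "spectrum", ref)
        if ref.ndim != 1:
            raise ValueError("MSC reference must be a single spectrum")
        if np.std(ref) == 0:
            raise ValueError("MSC reference has zero variance")


@dataclass(frozen=True)
class PreprocChain:
    """Ordered preprocessing steps with a catalogue method id (1..10).

    Step vocabulary: ``none``, ``sg_smooth``, ``sg_deriv``, ``snv``, ``msc``,
    ``detrend``.
    """

    method_id: int
    name: str
    steps: tuple[str, ...]
    sg_window: int = SG_WINDOW
    sg_polyorder: int = SG_POLYORDER
    detrend_degree: int = DETREND_DEGREE

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("SG window must be odd and > polyorder")
        known = {"none", "sg_smooth", "sg_deriv", "snv", "msc", "detrend"}
        unknown = set(self.steps) - known
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")

    @property
    def needs_msc_reference(self) -> bool:
        return "msc" in self.steps


#: the ten catalogue chains, in screening order. Ties in the screen are broken
#: by this order.
CHAIN_CATALOGUE: tuple[PreprocChain, ...] = (
    PreprocChain(1, "No preprocessing", ("none",)),
    PreprocChain(2, "SG smoothing", ("sg_smooth",)),
    PreprocChain(3, "SG first derivative", ("sg_deriv",)),
    PreprocChain(4, "SNV", ("snv",)),
    PreprocChain(5, "SNV + SG smoothing", ("snv", "sg_smooth")),
    PreprocChain(6, "SNV + SG first derivative", ("snv", "sg_deriv")),
    PreprocChain(7, "MSC", ("msc",)),
    PreprocChain(8, "MSC + SG smoothing", ("msc", "sg_smooth")),
    PreprocChain(9, "MSC + SG first derivative", ("msc", "sg_deriv")),
    PreprocChain(10, "Detrending", ("detrend",)),
)


def get_chain(method_id: int) -> PreprocChain:
    for chain in CHAIN_CATALOGUE:
        if chain.method_id == method_id:
            return chain
    raise KeyError(f"no preprocessing chain with method_id {method_id}")


# ---------------------------------------------------------------------------
# Elementary corrections
# ---------------------------------------------------------------------------

def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum (row).

    Uses the sample (n−1 denominator) standard deviation; every output row has
    mean 0 and standard deviation 1.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum at row {bad[0]}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc_fit(X_cal: np.ndarray) -> MscReference:
    """Fit the MSC reference: the mean spectrum of the calibration set only."""
    X_cal = np.asarray(X_cal, dtype=float)
    if X_cal.ndim != 2 or X_cal.shape[0] == 0:
        raise ValueError("need a non-empty calibration matrix")
    return MscReference(X_cal.mean(axis=0))


def msc_apply(X: np.ndarray, ref: MscReference) -> np.ndarray:
    """Multiplicative scatter correction against a fixed reference spectrum.

    Each spectrum s is regressed on the reference, s ≈ a·ref + b, and replaced
    by (s − b)/a, undoing per-sample multiplicative and additive scatter.
    """
    X = np.asarray(X, dtype=float)
    r = ref.spectrum
    if X.shape[1] != r.size:
        raise ValueError("spectrum length does not match MSC reference")
    rc = r - r.mean()
    denom = float(rc @ rc)
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    zero = np.flatnonzero(a == 0)
    if zero.size:
        raise ValueError(f"MSC slope is zero for row {zero[0]}")
    b = X.mean(axis=1) - a * r.mean()
    return (X - b[:, None]) / a[:, None]


def savitzky_golay(
    X: np.ndarray,
    grid: WavenumberGrid,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
    deriv: int = 0,
) -> np.ndarray:
    """Savitzky–Golay filtering along the wavenumber axis.

    Boundary windows are handled by evaluating the local polynomial fit, so
    the output keeps the full length p. For ``deriv >= 1`` the result is a
    derivative with respect to wavenumber (per cm⁻¹): because the storage
    order is *descending* in wavenumber, odd derivatives along the index axis
    are sign-flipped back to the physical axis.
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if window <= polyorder:
        raise ValueError("SG window must exceed the polynomial order")
    if deriv > polyorder:
        raise ValueError("derivative order cannot exceed the polynomial order")
    if X.shape[1] < window:
        raise ValueError("SG window longer than the spectrum")
    if not grid.is_uniform():
        raise ValueError("SG derivative scaling requires a uniform grid")
    out = savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=grid.spacing, axis=1, mode="interp",
    )
    if deriv % 2 == 1:
        out = -out  # index axis runs opposite to the wavenumber axis
    return out


def detrend(X: np.ndarray, degree: int = DETREND_DEGREE) -> np.ndarray:
    """Subtract each row's least-squares polynomial over the index axis."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if degree >= p:
        raise ValueError("polynomial degree must be < number of wavenumbers")
    t = np.linspace(-1.0, 1.0, p)
    basis = np.polynomial.polynomial.polyvander(t, degree)  # p × (degree+1)
    coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
    return X - (basis @ coef).T


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def apply_chain(
    X: np.ndarray,
    chain: PreprocChain,
    grid: WavenumberGrid,
    ref: MscReference | None = None,
) -> np.ndarray:
    """Apply a catalogue chain left-to-right (scatter correction first)."""
    if chain.needs_msc_reference and ref is None:
        raise ValueError(f"chain {chain.method_id} ({chain.name}) needs an MSC reference")
    out = np.asarray(X, dtype=float)
    for step in chain.steps:
        if step == "none":
            continue
        elif step == "snv":
            out = snv(out)
        elif step == "msc":
            out = msc_apply(out, ref)
        elif step == "sg_smooth":
            out = savitzky_golay(out, grid, chain.sg_window, chain.sg_polyorder, deriv=0)
        elif step == "sg_deriv":
            out = savitzky_golay(out, grid, chain.sg_window, chain.sg_polyorder, deriv=1)
        elif step == "detrend":
            out = detrend(out, chain.detrend_degree)
    return out


@dataclass(frozen=True)
class ScreenRow:
    """One screened chain: its CV and test-set PLS performance."""

    chain: PreprocChain
    n_components: int | None
    cv_report: EvalReport | None
    test_report: EvalReport | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def screen_preprocessing(
    ds_cal: Dataset,
    ds_test: Dataset,
    folds: FoldPlan,
    chains: Sequence[PreprocChain] = CHAIN_CATALOGUE,
    max_components: int = 15,
) -> list[ScreenRow]:
    """Rank preprocessing chains by the test-set R² of a PLS model.

    For each chain: fit the MSC reference (if needed) on the calibration set
    only, apply the chain to both sets, choose the PLS component count by
    5-fold RMSECV on the calibration set, and evaluate on the test set. Rows
    are sorted by test R² descending, ties broken by catalogue order; a CV-only
    ranking can be recovered from the per-row ``cv_report`` for users who do
    not want the prediction set to participate in method choice. Chains that
    fail on the data are kept in the output, flagged, and sorted last.
    """
    if set(ds_cal.sample_ids) & set(ds_test.sample_ids):
        raise ValueError("calibration and test sets must be disjoint")
    rows: list[ScreenRow] = []
    grid = ds_cal.spectra.grid
    for chain in chains:
        try:
            ref = msc_fit(ds_cal.X) if chain.needs_msc_reference else None
            Xc = apply_chain(ds_cal.X, chain, grid, ref)
            Xt = apply_chain(ds_test.X, chain, grid, ref)
            fit = fit_pls_cv(Xc, ds_cal.y, folds, max_components=max_components)
            cv_rep = evaluate(ds_cal.y, fit.oof_predictions, tag="cv")
            test_rep = evaluate(ds_test.y, fit.model.predict(Xt).ravel(), tag="test")
            rows.append(ScreenRow(chain, fit.n_components, cv_rep, test_rep))
        except ValueError as exc:
            rows.append(ScreenRow(chain, None, None, None, error=str(exc)))
    order = sorted(
        range(len(rows)),
        key=lambda i: (
            rows[i].failed,
            -(rows[i].test_report.r2 if not rows[i].failed else 0.0),
            rows[i].chain.method_id,
        ),
    )
    return [rows[i] for i in order]
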