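"""Folin–Ciocalteu quantification arithmetic.

Total polyphenol content (TPC) is referenced against a gallic acid standard
curve, absorbance A at 765 nm versus concentration C in mg/L:

    A = slope · C + intercept

and converted to g gallic acid equivalents per 100 g dry weight via

    TPC = (A − intercept) · V · D / (slope · m · 10)

with V the extraction volume (mL), D the dilution factor, and m the sample
mass (g). The ×10 divisor carries the unit conversion from (mg/L · mL / g)
to g GAE/100 g DW as conventionally printed; absorbances below the intercept
correspond to physically meaningless negative concentrations and are clamped
to TPC = 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "TpcInputs", "fit_standard_curve", "tpc"]


@dataclass(frozen=True)
class StandardCurve:
    """Linear gallic acid calibration: absorbance per (mg/L) slope + intercept."""

    slope: float
    intercept: float
    r2: float
    linear_range_mg_l: tuple[float, float] = (0.0, 10.0)
    lod_mg_l: float = 0.05

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be positive")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    def concentration(self, absorbance: float) -> float:
        """Invert the curve: C = (A − intercept)/slope in mg/L."""
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class TpcInputs:
    """Assay readout and gravimetric factors for one sample."""

    absorbance: float
    volume_ml: float
    dilution: float
    mass_g: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("extraction volume must be positive")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.mass_g <= 0:
            raise ValueError("sample mass must be positive")


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """Ordinary least-squares line through the standard points."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 2:
        raise ValueError("need >= 2 matching standard points")
    if np.ptp(c) == 0:
        raise ValueError("standard concentrations are all equal")
    fit = stats.linregress(c, a)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue**2))


def tpc(inputs: TpcInputs, curve: StandardCurve) -> float:
    """TPC in g GAE/100 g DW: (A − intercept)·V·D / (slope·m·10).

    Linear in (A − intercept), V and D; inversely linear in m. A below-intercept
    absorbance yields 0 with a warning.
    """
    numerator = inputs.absorbance - curve.intercept
    if numerator < 0:
        warnings.warn(
            "absorbance below the standard-curve intercept; clamping TPC to 0",
            stacklevel=2,
        )
        return 0.0
    return numerator * inputs.volume_ml * inputs.dilution / (
        curve.slope * inputs.mass_g * 10.0
    )
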