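"""Standard-curve absolute quantification.

Two calibrations are implemented:

* **UPLC-ESI-MS/MS (MRM)**: linear response curves (integrated peak area
  vs amount) for the nucleosides 6mA (transition m/z 266 -> 150) and dA
  (252 -> 136); sample areas are inverted through their curves and the
  6mA/dA amount ratio reported in parts per million.
* **qPCR**: a standard curve of Ct against log10 template copies
  (ideal efficiency gives slope -3.32 cycles per decade); a sample Ct is
  inverted to total copies and divided by the number of cells extracted
  (500,000 by default) to give transcript copies per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "RatioResult",
    "fit_calibration",
    "quantify_ratio_ppm",
    "copies_per_cell",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordinary least-squares line ``response = slope * amount + intercept``."""

    slope: float
    intercept: float
    r2: float
    analyte: str = ""
    x_units: str = ""
    y_units: str = ""

    def invert(self, response: float) -> float:
        """Amount producing the given response."""
        if self.slope == 0:
            raise ValueError("cannot invert a zero-slope curve")
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class RatioResult:
    ppm: float
    below_lod: bool = False


def fit_calibration(
    amounts,
    responses,
    through_origin: bool = False,
    analyte: str = "",
    x_units: str = "",
    y_units: str = "",
) -> CalibrationCurve:
    """Fit a linear calibration curve by ordinary least squares.

    Requires at least two distinct amounts. ``through_origin`` forces the
    intercept to zero (off by default).
    """
    x = np.asarray(amounts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 (amount, response) pairs")
    if np.allclose(x, x[0]):
        raise ValueError("all standard amounts are identical")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r2=max(0.0, min(1.0, r2)),
        analyte=analyte,
        x_units=x_units,
        y_units=y_units,
    )


def quantify_ratio_ppm(
    area_6ma: float,
    area_da: float,
    curve_6ma: CalibrationCurve,
    curve_da: CalibrationCurve,
) -> RatioResult:
    """6mA/dA amount ratio in ppm from MRM peak areas.

    Each area is inverted through its analyte's curve. A 6mA amount at or
    below zero (area at or below the curve intercept) is clamped to 0 ppm
    and flagged below the limit of detection — matching "undetectable"
    baseline levels. A non-positive dA amount is an error: the denominator
    nucleoside must be quantifiable.
    """
    if area_6ma < 0 or area_da < 0:
        raise ValueError("peak areas must be non-negative")
    amount_da = curve_da.invert(area_da)
    if amount_da <= 0:
        raise ValueError("dA amount is non-positive; sample cannot be quantified")
    amount_6ma = curve_6ma.invert(area_6ma)
    if amount_6ma <= 0:
        return RatioResult(ppm=0.0, below_lod=True)
    return RatioResult(ppm=amount_6ma / amount_da * 1e6, below_lod=False)


def copies_per_cell(
    ct: float,
    ct_curve: CalibrationCurve,
    n_cells: int = 500_000,
) -> float:
    """Transcript copies per cell from a sample Ct and a qPCR standard curve.

    ``ct_curve`` is fitted as Ct against log10(copies); the sample's total
    copies are ``10 ** ((ct - intercept) / slope)``, divided by the number
    of cells the RNA came from.
    """
    if ct_curve.slope == 0:
        raise ValueError("qPCR curve slope must be non-zero")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    total = 10.0 ** ((ct - ct_curve.intercept) / ct_curve.slope)
    return total / n_cells
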