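"""Internal-standard-ratio calibration and S/N-based sensitivity limits.

Quantification uses the analyte/IS peak-area ratio so that preparation
and injection variability cancels. The calibration model is an ordinary
least-squares line, ratio = slope * concentration + intercept, fit over
the spiking levels; an optional 1/x^2 weighting is available but off by
default. LOD and LLOQ are the concentrations whose predicted
signal-to-noise reaches 3:1 and 10:1 under the S/N definition of the
chromatography module (S/N = 2*height/noise_excursion), hence

    LOD  = 3  * noise / (2 * height_slope)
    LLOQ = 10 * noise / (2 * height_slope)

with ``height_slope`` the peak-height response per ug/mL. Heights, not
areas, set the limits because S/N is a height quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SensitivityLimits",
    "BackCalculated",
    "fit_calibration",
    "predict",
    "back_calculate",
    "estimate_limits",
    "InvalidRatioError",
    "DegenerateCurveError",
]


class InvalidRatioError(ValueError):
    """An internal-standard area was zero or negative."""


class DegenerateCurveError(ValueError):
    """The calibration slope is zero; back-calculation impossible."""


@dataclass(frozen=True)
class CalibrationCurve:
    analyte_id: str
    slope: float
    intercept: float
    r_squared: float
    range_low: float
    range_high: float
    n_levels: int

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")


@dataclass(frozen=True)
class SensitivityLimits:
    """LOD (S/N 3:1) and LLOQ (S/N 10:1) in ug/mL."""

    lod: float
    lloq: float

    def __post_init__(self) -> None:
        if not 0 < self.lod < self.lloq:
            raise ValueError("require 0 < lod < lloq")


@dataclass(frozen=True)
class BackCalculated:
    """A back-calculated concentration with its range flag."""

    concentration: float
    in_range: bool


def fit_calibration(
    levels: Sequence[tuple[float, float, float]],
    analyte_id: str = "analyte",
    weighting: str | None = None,
) -> CalibrationCurve:
    """OLS fit of the analyte/IS area ratio against concentration.

    ``levels`` holds (concentration ug/mL, analyte_area, is_area)
    triples. ``weighting=\"1/x2\"`` switches to 1/concentration^2
    weighted least squares (all levels must then be nonzero).
    """
    if len(levels) < 2:
        raise ValueError("need at least 2 calibration levels")
    conc = np.array([l[0] for l in levels], dtype=float)
    a_area = np.array([l[1] for l in levels], dtype=float)
    is_area = np.array([l[2] for l in levels], dtype=float)
    if np.any(is_area <= 0):
        raise InvalidRatioError("internal-standard areas must be > 0")
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    ratio = a_area / is_area

    if weighting is None:
        fit = stats.linregress(conc, ratio)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
        if not np.isfinite(r2):  # flat response: no explainable variance
            r2 = 0.0
    elif weighting == "1/x2":
        if np.any(conc == 0):
            raise ValueError("1/x2 weighting needs nonzero concentrations")
        w = 1.0 / conc**2
        coef = np.polynomial.polynomial.polyfit(conc, ratio, 1, w=np.sqrt(w))
        intercept, slope = float(coef[0]), float(coef[1])
        # weighted coefficient of determination
        resid = ratio - (slope * conc + intercept)
        ybar = np.sum(w * ratio) / np.sum(w)
        r2 = float(1.0 - np.sum(w * resid**2) / np.sum(w * (ratio - ybar) ** 2))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    return CalibrationCurve(
        analyte_id=analyte_id,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        range_low=float(conc.min()),
        range_high=float(conc.max()),
        n_levels=int(np.unique(conc).size),
    )


def predict(curve: CalibrationCurve, concentration: float) -> float:
    """Expected area ratio at a concentration (the fitted line)."""
    return curve.slope * concentration + curve.intercept


def back_calculate(curve: CalibrationCurve, ratio: float) -> BackCalculated:
    """Invert the calibration line: (ratio - intercept) / slope.

    Out-of-range results are flagged, not rejected; LLOQ censoring is
    applied downstream.
    """
    if curve.slope == 0:
        raise DegenerateCurveError("zero slope; cannot back-calculate")
    conc = (ratio - curve.intercept) / curve.slope
    return BackCalculated(
        concentration=float(conc),
        in_range=bool(curve.range_low <= conc <= curve.range_high),
    )


def estimate_limits(
    height_response_slope: float, noise_excursion: float
) -> SensitivityLimits:
    """LOD and LLOQ from the height response and blank noise excursion."""
    if height_response_slope <= 0 or noise_excursion <= 0:
        raise ValueError("both inputs must be > 0")
    lod = 3.0 * noise_excursion / (2.0 * height_response_slope)
    lloq = 10.0 * noise_excursion / (2.0 * height_response_slope)
    return SensitivityLimits(lod=lod, lloq=lloq)
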