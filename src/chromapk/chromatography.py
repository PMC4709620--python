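"""Peak detection, integration and system-suitability metrics.

The reported quantities are the pharmacopeial system-suitability
numbers computed per analyte peak:

* plate count (column efficiency), half-height convention:
  ``N = 5.54 * (tR / W50)**2``
* tailing factor, USP 5%-height convention:
  ``T = W5 / (2 * f5)`` with ``f5`` the leading-edge-to-apex distance
* resolution to the previous peak, baseline-width convention:
  ``Rs = 2 * (tR2 - tR1) / (Wb1 + Wb2)`` with ``Wb = 1.699 * W50``
  (the Gaussian 4-sigma base width vs the 2.3548-sigma half-height width)
* signal-to-noise, ``S/N = 2 * height / noise`` where the noise is the
  peak-to-peak excursion of a linearly detrended blank region.

Acceptance limits follow the usual guideline values: Rs > 2.0 (strict),
T <= 2.0 (inclusive), N > 2000 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Chromatogram",
    "PeakMeasurement",
    "SSTLimits",
    "SSTReport",
    "detect_peaks",
    "plate_count",
    "tailing_factor",
    "resolution",
    "signal_to_noise",
    "sst_evaluate",
    "ChromatographyError",
    "MissingAnalyteError",
    "DegeneratePeakError",
    "UndefinedSNRError",
    "CoElutionWarning",
    "GAUSSIAN_FWHM_SIGMA",
    "BASE_TO_HALF_WIDTH",
    "PLATE_COUNT_FACTOR",
]

# Pharmacopeial constants; each convention is a single switchable number.
GAUSSIAN_FWHM_SIGMA = float(2.0 * np.sqrt(2.0 * np.log(2.0)))  # unit-Gaussian FWHM
PLATE_COUNT_FACTOR = 5.54          # half-height plate-count prefactor
BASE_TO_HALF_WIDTH = 4.0 / GAUSSIAN_FWHM_SIGMA  # = 1.6986, Wb / W50
PEAK_BOUND_FRACTION = 0.01         # integration bounds at 1% of apex height


class ChromatographyError(ValueError):
    """Base class for chromatogram processing failures."""


class MissingAnalyteError(ChromatographyError):
    """No peak found inside a required retention window."""


class DegeneratePeakError(ChromatographyError):
    """A peak width or asymmetry input collapsed to zero."""


class UndefinedSNRError(ChromatographyError):
    """Blank region carries no measurable noise."""


class CoElutionWarning(UserWarning):
    """Two peaks share a retention time; resolution is zero."""


@dataclass(frozen=True)
class Chromatogram:
    """A single-channel detector trace: time in minutes, signal in
    arbitrary absorbance units."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a chromatogram needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class PeakMeasurement:
    """One integrated peak.

    ``area`` is baseline-corrected and reported in signal*seconds (the
    time axis is minutes; the integrator applies the 60 s/min factor).
    ``front_at_5pct`` is the distance from the leading edge at 5% height
    to the apex, the asymmetry input of the USP tailing factor.
    """

    analyte_id: str
    retention_time: float
    area: float
    height: float
    width_at_half: float
    width_at_5pct: float
    front_at_5pct: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.width_at_half <= 0 or self.width_at_5pct <= 0:
            raise ValueError("widths must be > 0")
        if self.front_at_5pct > self.width_at_5pct:
            raise ValueError("front_at_5pct cannot exceed width_at_5pct")


@dataclass(frozen=True)
class SSTLimits:
    """Guideline acceptance limits; boundary semantics as stated."""

    resolution_min: float = 2.0   # strict: Rs > limit
    tailing_max: float = 2.0      # inclusive: T <= limit
    plate_count_min: float = 2000.0  # strict: N > limit


@dataclass
class SSTReport:
    """Per-analyte system-suitability table with pass flags."""

    rows: list[dict]
    limits: SSTLimits = field(default_factory=SSTLimits)

    @property
    def all_pass(self) -> bool:
        return all(r["pass"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _parabolic_apex(t: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """Refine apex position/height with a 3-point parabola around index j."""
    if j == 0 or j == y.size - 1:
        return float(t[j]), float(y[j])
    denom = y[j - 1] - 2.0 * y[j] + y[j + 1]
    if denom >= 0:  # not locally concave; keep the sample apex
        return float(t[j]), float(y[j])
    delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = 0.5 * (t[j + 1] - t[j - 1])
    t_apex = float(t[j] + delta * dt)
    h_apex = float(y[j] - 0.25 * (y[j - 1] - y[j + 1]) * delta)
    return t_apex, h_apex


def _cross_left(t, y, j, level):
    """Interpolated time where y falls to `level` scanning left from j."""
    for i in range(j - 1, -1, -1):
        if y[i] <= level:
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _cross_right(t, y, j, level):
    for i in range(j + 1, y.size):
        if y[i] <= level:
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def _measure_peak(
    chrom: Chromatogram, apex: int, left_lim: int, right_lim: int, analyte_id: str
) -> PeakMeasurement | None:
    """Integrate one peak between search limits.

    Bounds are placed where the baseline-corrected signal falls to 1% of
    the apex height or at the local minimum toward the neighbouring
    peak, whichever comes first; the baseline is the straight line
    between the bounds.
    """
    t, s = chrom.time, chrom.signal
    # baseline anchors: minima of the raw signal within the search gaps
    # toward the neighbouring apexes (or the trace ends)
    lo0 = left_lim + int(np.argmin(s[left_lim : apex + 1])) if apex > left_lim else left_lim
    hi0 = apex + int(np.argmin(s[apex : right_lim + 1])) if right_lim > apex else right_lim
    if lo0 == hi0:
        return None
    base = np.interp(t[lo0:hi0 + 1], [t[lo0], t[hi0]], [s[lo0], s[hi0]])
    corr_full = s[lo0:hi0 + 1] - base
    j_full = apex - lo0
    h0 = corr_full[j_full]
    if h0 <= 0:
        return None

    # integration limits: where the corrected signal falls to 1% of the
    # apex or the baseline anchor, whichever comes first
    thresh = PEAK_BOUND_FRACTION * h0
    lo, hi = lo0, hi0
    for i in range(j_full - 1, -1, -1):
        if corr_full[i] <= thresh:
            lo = lo0 + i
            break
    for i in range(j_full + 1, corr_full.size):
        if corr_full[i] <= thresh:
            hi = lo0 + i
            break

    tt = t[lo:hi + 1]
    corr = corr_full[lo - lo0 : hi - lo0 + 1]
    j = apex - lo
    t_apex, h_apex = _parabolic_apex(tt, corr, j)
    if h_apex <= 0:
        return None

    area_min = float(np.trapezoid(corr, tt))  # signal*minutes
    widths = {}
    for frac in (0.5, 0.05):
        lvl = frac * h_apex
        tl = _cross_left(tt, corr, j, lvl)
        tr = _cross_right(tt, corr, j, lvl)
        if tl is None or tr is None:
            return None
        widths[frac] = (tl, tr)
    w50 = widths[0.5][1] - widths[0.5][0]
    w5 = widths[0.05][1] - widths[0.05][0]
    front5 = t_apex - widths[0.05][0]
    if w50 <= 0 or w5 <= 0 or front5 <= 0:
        return None
    return PeakMeasurement(
        analyte_id=analyte_id,
        retention_time=t_apex,
        area=area_min * 60.0,
        height=h_apex,
        width_at_half=w50,
        width_at_5pct=w5,
        front_at_5pct=front5,
    )


def detect_peaks(
    chrom: Chromatogram,
    min_height: float,
    expected: dict[str, tuple[float, float]] | None = None,
) -> list[PeakMeasurement]:
    """Locate and integrate all peaks above ``min_height``.

    Local maxima come from :func:`scipy.signal.find_peaks`; each apex is
    then resolved to a full :class:`PeakMeasurement` with a local linear
    baseline, trapezoidal area and interpolated widths at 50% and 5% of
    the corrected height. Baseline correction makes the result invariant
    to a uniform signal offset.

    ``expected`` maps analyte labels to ``(t_lo, t_hi)`` retention
    windows; each window keeps only its highest apex and an empty window
    raises :class:`MissingAnalyteError`.
    """
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    t, s = chrom.time, chrom.signal
    floor = float(np.median(s))
    # prominence filtering keeps baseline-noise maxima from fragmenting peaks
    apexes, _ = sps.find_peaks(s, height=floor + min_height, prominence=min_height)
    apexes = list(int(a) for a in apexes)

    measurements: list[PeakMeasurement] = []
    for k, apex in enumerate(apexes):
        left_lim = apexes[k - 1] if k > 0 else 0
        right_lim = apexes[k + 1] if k + 1 < len(apexes) else t.size - 1
        m = _measure_peak(chrom, apex, left_lim, right_lim, analyte_id=f"peak{k+1}")
        if m is not None and m.height >= min_height:
            measurements.append(m)

    if expected is None:
        return measurements

    selected: list[PeakMeasurement] = []
    for analyte, (lo, hi) in expected.items():
        in_window = [m for m in measurements if lo <= m.retention_time <= hi]
        if not in_window:
            raise MissingAnalyteError(
                f"no peak above {min_height} found for {analyte!r} in "
                f"window [{lo}, {hi}] min"
            )
        best = max(in_window, key=lambda m: m.height)
        selected.append(
            PeakMeasurement(
                analyte_id=analyte,
                retention_time=best.retention_time,
                area=best.area,
                height=best.height,
                width_at_half=best.width_at_half,
                width_at_5pct=best.width_at_5pct,
                front_at_5pct=best.front_at_5pct,
            )
        )
    selected.sort(key=lambda m: m.retention_time)
    return selected


def plate_count(peak: PeakMeasurement) -> float:
    """Column efficiency N by the half-height method, 5.54*(tR/W50)^2."""
    if peak.width_at_half <= 0:
        raise DegeneratePeakError("width_at_half must be > 0")
    return PLATE_COUNT_FACTOR * (peak.retention_time / peak.width_at_half) ** 2


def tailing_factor(peak: PeakMeasurement) -> float:
    """USP tailing factor T = W5 / (2*f5); 1.0 for a symmetric peak."""
    if peak.front_at_5pct <= 0:
        raise DegeneratePeakError("front_at_5pct must be > 0")
    return peak.width_at_5pct / (2.0 * peak.front_at_5pct)


def resolution(peak1: PeakMeasurement, peak2: PeakMeasurement) -> float:
    """Baseline-width resolution Rs = 2*(tR2 - tR1)/(Wb1 + Wb2).

    Base widths are approximated from the half-height widths via the
    Gaussian relation Wb = 1.699 * W50.
    """
    dt = peak2.retention_time - peak1.retention_time
    if dt < 0:
        raise ValueError("peak2 must elute after peak1")
    if dt == 0:
        warnings.warn(
            "peaks share a retention time; Rs = 0", CoElutionWarning, stacklevel=2
        )
        return 0.0
    wb1 = BASE_TO_HALF_WIDTH * peak1.width_at_half
    wb2 = BASE_TO_HALF_WIDTH * peak2.width_at_half
    return 2.0 * dt / (wb1 + wb2)


def signal_to_noise(
    peak: PeakMeasurement,
    chrom: Chromatogram,
    blank_region: tuple[float, float],
) -> float:
    """S/N = 2*height / peak-to-peak excursion of the detrended blank.

    The blank region (min) must hold at least 20 samples and no peak;
    a straight line is removed before the excursion is measured so slow
    baseline drift does not inflate the noise estimate.
    """
    lo, hi = blank_region
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if int(mask.sum()) < 20:
        raise ValueError("blank region must contain at least 20 samples")
    blank = chrom.signal[mask]
    detrended = sps.detrend(blank, type="linear")
    noise = float(np.ptp(detrended))
    if noise <= 0:
        raise UndefinedSNRError("blank region has zero excursion; S/N undefined")
    return 2.0 * peak.height / noise


def sst_evaluate(
    peaks: list[PeakMeasurement], limits: SSTLimits | None = None
) -> SSTReport:
    """System-suitability report for a run: N, T and Rs per analyte.

    Peaks must be ordered by retention time; resolution is computed to
    the previous peak, so the first row (and a single-peak run) carries
    none. Pass flags apply the guideline boundary semantics: Rs strictly
    above its limit, T at or below, N strictly above.
    """
    limits = limits or SSTLimits()
    if any(
        p2.retention_time < p1.retention_time
        for p1, p2 in zip(peaks, peaks[1:])
    ):
        raise ValueError("peaks must be ordered by retention time")
    if len(peaks) < 2:
        warnings.warn(
            "fewer than 2 peaks: resolution omitted from the report",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for i, p in enumerate(peaks):
        n = plate_count(p)
        t_f = tailing_factor(p)
        rs = resolution(peaks[i - 1], p) if i > 0 else None
        n_ok = n > limits.plate_count_min
        t_ok = t_f <= limits.tailing_max
        rs_ok = (rs > limits.resolution_min) if rs is not None else True
        rows.append(
            {
                "analyte_id": p.analyte_id,
                "retention_time": p.retention_time,
                "plate_count": n,
                "tailing_factor": t_f,
                "resolution": rs,
                "plate_count_pass": n_ok,
                "tailing_pass": t_ok,
                "resolution_pass": rs_ok,
                "pass": n_ok and t_ok and rs_ok,
            }
        )
    return SSTReport(rows=rows, limits=limits)
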