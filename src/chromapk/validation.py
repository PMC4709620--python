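"""Accuracy, precision, stability, robustness and degradation arithmetic.

Bioanalytical acceptance follows the +/-15% rule: a QC or stability set
passes when recovery (100 * mean_found / nominal) is within 15 points of
100% and the relative standard deviation (100 * SD / mean) is at most
15%. Both boundaries are inclusive. Sample SD (n-1 denominator) is used
throughout. Reports round recovery to whole percent and RSD to two
decimals for display; full precision is preserved internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCSet",
    "ValidationRow",
    "recovery",
    "rsd",
    "rsd_from_moments",
    "assess_qc",
    "assess_stability",
    "robustness_summary",
    "degradation_recovery",
    "ACCEPTANCE_TOLERANCE_PCT",
]

ACCEPTANCE_TOLERANCE_PCT = 15.0


@dataclass(frozen=True)
class QCSet:
    """Replicate measurements of one spiked QC sample."""

    analyte_id: str
    nominal: float
    measured: tuple[float, ...]
    period: str = "intraday"  # intraday | interday | short_term | long_term

    def __post_init__(self) -> None:
        if self.nominal <= 0:
            raise ValueError("nominal must be > 0")
        if len(self.measured) < 2:
            raise ValueError("need >= 2 replicates for SD/RSD")
        object.__setattr__(self, "measured", tuple(float(v) for v in self.measured))


@dataclass(frozen=True)
class ValidationRow:
    """One accuracy/precision table row with its pass flag."""

    analyte_id: str
    period: str
    nominal: float
    mean_found: float
    sd: float
    recovery_pct: float
    rsd_pct: float
    n: int
    passed: bool

    def rounded(self) -> dict:
        """Display form: recovery to whole percent, RSD to 2 decimals."""
        return {
            "analyte_id": self.analyte_id,
            "period": self.period,
            "nominal": self.nominal,
            "mean_found": round(self.mean_found, 2),
            "sd": round(self.sd, 2),
            "recovery_pct": round(self.recovery_pct),
            "rsd_pct": round(self.rsd_pct, 2),
            "n": self.n,
            "pass": self.passed,
        }


def recovery(nominal: float, mean_found: float) -> float:
    """Accuracy as percent recovery, 100 * mean_found / nominal."""
    if nominal <= 0:
        raise ValueError("nominal must be > 0")
    return 100.0 * mean_found / nominal


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) of replicates, sample SD (n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values for a sample SD")
    mean = float(v.mean())
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return 100.0 * float(v.std(ddof=1)) / mean


def rsd_from_moments(mean: float, sd: float) -> float:
    """RSD (%) from a printed mean +/- SD pair."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / mean


def _assess(
    analyte_id: str, period: str, nominal: float, measured: Sequence[float]
) -> ValidationRow:
    v = np.asarray(measured, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    rec = recovery(nominal, mean)
    prec = rsd_from_moments(mean, sd)
    passed = (
        abs(rec - 100.0) <= ACCEPTANCE_TOLERANCE_PCT
        and prec <= ACCEPTANCE_TOLERANCE_PCT
    )
    return ValidationRow(
        analyte_id=analyte_id,
        period=period,
        nominal=nominal,
        mean_found=mean,
        sd=sd,
        recovery_pct=rec,
        rsd_pct=prec,
        n=int(v.size),
        passed=passed,
    )


def assess_qc(qc: QCSet) -> ValidationRow:
    """Accuracy/precision row for a QC replicate set with the +/-15% rule."""
    return _assess(qc.analyte_id, qc.period, qc.nominal, qc.measured)


def assess_stability(
    reference_nominal: float,
    stored_measurements: Sequence[float],
    condition: str,
    analyte_id: str = "analyte",
) -> ValidationRow:
    """Stability row: same arithmetic, the +/-15% change rule.

    A mean drop of exactly 15% still passes (inclusive boundary).
    ``condition`` is an opaque label such as ``short_term`` or
    ``long_term``.
    """
    if len(stored_measurements) < 2:
        raise ValueError("need >= 2 stored replicates")
    return _assess(analyte_id, condition, reference_nominal, stored_measurements)


def robustness_summary(
    runs: Sequence[tuple[str, dict[str, Sequence[float]]]],
) -> pd.DataFrame:
    """Retention-time variability under deliberately varied conditions.

    ``runs`` holds (condition label, {analyte: replicate retention
    times}) pairs — e.g. flow rates 0.9/1.0/1.1 mL/min or buffer pH
    2.6/2.8. Returns per condition and analyte the mean retention time,
    SD and RSD%. All runs must report the same analyte set.
    """
    if not runs:
        raise ValueError("no runs given")
    analytes = set(runs[0][1])
    rows = []
    for condition, per_analyte in runs:
        if set(per_analyte) != analytes:
            raise ValueError(
                f"condition {condition!r} reports analytes {sorted(per_analyte)}, "
                f"expected {sorted(analytes)}"
            )
        for analyte, times in per_analyte.items():
            t = np.asarray(times, dtype=float)
            if t.size < 2:
                raise ValueError("need >= 2 replicates per condition")
            rows.append(
                {
                    "condition": condition,
                    "analyte_id": analyte,
                    "mean_tr": float(t.mean()),
                    "sd_tr": float(t.std(ddof=1)),
                    "rsd_pct": 100.0 * float(t.std(ddof=1)) / float(t.mean()),
                    "n": int(t.size),
                }
            )
    return pd.DataFrame(rows)


def degradation_recovery(reference_area: float, stressed_area: float) -> float:
    """Percent of the parent peak surviving a stress condition."""
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    if stressed_area < 0:
        raise ValueError("stressed_area must be >= 0")
    return 100.0 * stressed_area / reference_area
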