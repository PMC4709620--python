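"""Delimited-text and key-value I/O for every pipeline artifact.

All tabular artifacts are tab-separated text with headers; scalar
records (profile metadata, calibration-curve reports) are YAML. Nothing
here is binary, so every artifact diffs and versions cleanly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chromapk.calibration import CalibrationCurve
from chromapk.chromatography import Chromatogram, SSTReport
from chromapk.pk import ConcentrationTimeProfile, PKResult
from chromapk.validation import ValidationRow

__all__ = [
    "write_chromatogram",
    "read_chromatogram",
    "write_profile",
    "read_profile",
    "write_calibration_table",
    "read_calibration_table",
    "write_curve",
    "read_curve",
    "write_qc_table",
    "read_qc_table",
    "write_validation_report",
    "write_sst_report",
    "write_pk_report",
]


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Two-column TSV: time_min, signal."""
    df = pd.DataFrame({"time_min": chrom.time, "signal": chrom.signal})
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_chromatogram(path: str | Path) -> Chromatogram:
    df = pd.read_csv(path, sep="\t")
    return Chromatogram(
        time=df["time_min"].to_numpy(float), signal=df["signal"].to_numpy(float)
    )


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_profile(profile: ConcentrationTimeProfile, path: str | Path) -> None:
    """TSV (time_h, conc_ug_per_mL, censored_flag) + YAML sidecar metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": profile.times,
            "conc_ug_per_mL": profile.concentrations,
            "censored_flag": [int(c) for c in profile.censored],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "analyte": profile.analyte_id,
        "subject": profile.subject_id,
        "dose_mg": float(profile.dose_mg),
        "lloq": float(profile.lloq),
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_profile(path: str | Path) -> ConcentrationTimeProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = yaml.safe_load(_meta_path(path).read_text())
    return ConcentrationTimeProfile(
        analyte_id=str(meta["analyte"]),
        subject_id=str(meta["subject"]),
        dose_mg=float(meta["dose_mg"]),
        times=tuple(df["time_h"].astype(float)),
        concentrations=tuple(df["conc_ug_per_mL"].astype(float)),
        censored=tuple(bool(x) for x in df["censored_flag"]),
        lloq=float(meta["lloq"]),
    )


def write_calibration_table(
    rows: list[tuple[float, float, float]], analyte_id: str, path: str | Path
) -> None:
    """TSV: level_conc, analyte_area, is_area, analyte_id."""
    df = pd.DataFrame(rows, columns=["level_conc", "analyte_area", "is_area"])
    df["analyte_id"] = analyte_id
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_calibration_table(path: str | Path) -> tuple[list[tuple[float, float, float]], str]:
    df = pd.read_csv(path, sep="\t")
    rows = [
        (float(r.level_conc), float(r.analyte_area), float(r.is_area))
        for r in df.itertuples()
    ]
    analyte = str(df["analyte_id"].iloc[0]) if "analyte_id" in df else "analyte"
    return rows, analyte


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Key-value record mirroring a regression-equation report."""
    rec = {
        "analyte": curve.analyte_id,
        "slope": float(curve.slope),
        "intercept": float(curve.intercept),
        "r_squared": float(curve.r_squared),
        "range_low": float(curve.range_low),
        "range_high": float(curve.range_high),
        "n_levels": int(curve.n_levels),
        "equation": f"y = {curve.slope:.4f}x + {curve.intercept:.4f}",
    }
    Path(path).write_text(yaml.safe_dump(rec, sort_keys=False))


def read_curve(path: str | Path) -> CalibrationCurve:
    rec = yaml.safe_load(Path(path).read_text())
    return CalibrationCurve(
        analyte_id=str(rec["analyte"]),
        slope=float(rec["slope"]),
        intercept=float(rec["intercept"]),
        r_squared=float(rec["r_squared"]),
        range_low=float(rec["range_low"]),
        range_high=float(rec["range_high"]),
        n_levels=int(rec["n_levels"]),
    )


def write_qc_table(qc_rows: pd.DataFrame, path: str | Path) -> None:
    """Long-format TSV: analyte_id, period, nominal, measured."""
    qc_rows.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qc_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_validation_report(rows: list[ValidationRow], path: str | Path) -> None:
    """Accuracy/precision table with the display rounding of the report."""
    pd.DataFrame([r.rounded() for r in rows]).to_csv(path, sep="\t", index=False)


def write_sst_report(report: SSTReport, path: str | Path) -> None:
    df = report.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_pk_report(results: list[PKResult], path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in results]).to_csv(path, sep="\t", index=False)
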