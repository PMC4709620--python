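"""Configuration and stage orchestration for the whole assay pipeline.

One YAML config is the single source of truth for analyte metadata
(retention windows, calibration levels and response lines, QC levels),
SST limits, the plasma sampling schedule, and the simulated patients'
ground-truth kinetics. Stages communicate through the text artifacts of
:mod:`chromapk.io`, so each stage is independently runnable and
testable:

``simulate`` -> ``sst`` / ``calibrate`` / ``validate`` / ``pk``

Every run writes a manifest (config hash, seed, package version) next
to its reports; same config + seed reproduces every table byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from chromapk import io as ckio
from chromapk.calibration import estimate_limits, fit_calibration
from chromapk.chromatography import (
    ChromatographyError,
    SSTLimits,
    detect_peaks,
    signal_to_noise,
    sst_evaluate,
)
from chromapk.pk import PKConfig, PKError, analyze_profile, tmax_model
from chromapk.synthetic import (
    BatemanParams,
    PeakSpec,
    SamplingSchedule,
    generate_chromatogram,
    generate_profile,
    generate_qc_replicates,
)
from chromapk.validation import (
    QCSet,
    assess_qc,
    assess_stability,
    degradation_recovery,
    robustness_summary,
)

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "ka_from_tmax", "STAGES"]

log = logging.getLogger("chromapk")

STAGES = ("simulate", "sst", "calibrate", "validate", "pk", "all")


class ConfigError(ValueError):
    """Configuration failed validation; the message names the field."""


def ka_from_tmax(ke: float, tmax: float) -> float:
    """Absorption rate constant implied by Ke and the model peak time.

    Inverts tmax = ln(Ka/Ke)/(Ka - Ke) for Ka > Ke; requires
    tmax < 1/Ke (the Ka -> Ke limit of the peak time).
    """
    if ke <= 0 or tmax <= 0:
        raise ValueError("ke and tmax must be > 0")
    if tmax >= 1.0 / ke:
        raise ValueError(f"tmax must be < 1/Ke = {1.0 / ke:.3g} h for Ka > Ke")
    lo, hi = ke * (1 + 1e-9), 1e4
    return float(brentq(lambda ka: tmax_model(ka, ke) - tmax, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# configuration

@dataclass
class AnalyteConfig:
    label: str
    retention_time: float                       # min
    window: tuple[float, float]                 # retention window, min
    lloq: float = 0.0                           # ug/mL
    calibration_levels: tuple[float, ...] = ()  # ug/mL
    calibration_slope: float = 0.0              # ratio per ug/mL
    calibration_intercept: float = 0.0
    qc_levels: tuple[float, ...] = ()           # ug/mL
    qc_true_recovery: float = 0.96
    qc_cv: float = 0.04
    peak_tau: float = 0.0                       # min, EMG tail of the sim peak


@dataclass
class PipelineConfig:
    seed: int = 0
    noise_cv: float = 0.05
    schedule: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 3.0, 6.0, 9.0, 12.0)
    sst_limits: SSTLimits = field(default_factory=SSTLimits)
    duration_min: float = 20.0
    sampling_rate_hz: float = 5.0
    baseline_noise_sd: float = 0.002
    peak_sigma_min: float = 0.05
    peak_area: float = 50.0
    terminal_rule: str = "after_tmax"
    analytes: dict[str, AnalyteConfig] = field(default_factory=dict)
    # patient -> analyte -> {ke (1/h), tmax (h), cmax (ug/mL), dose_mg}
    patients: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    stability: tuple[dict, ...] = ()
    degradation: tuple[dict, ...] = ()

    def validate(self) -> None:
        labels = list(self.analytes)
        if len(set(labels)) != len(labels):
            raise ConfigError("analytes: duplicate labels")
        for lab, a in self.analytes.items():
            if a.retention_time <= 0:
                raise ConfigError(f"analytes.{lab}.retention_time must be > 0")
            lo, hi = a.window
            if not lo < a.retention_time < hi:
                raise ConfigError(
                    f"analytes.{lab}.window must bracket its retention time"
                )
        for lim_field in ("resolution_min", "tailing_max", "plate_count_min"):
            if getattr(self.sst_limits, lim_field) <= 0:
                raise ConfigError(f"sst_limits.{lim_field} must be > 0")
        for patient, per_analyte in self.patients.items():
            for lab in per_analyte:
                if lab not in self.analytes:
                    raise ConfigError(
                        f"patients.{patient}: undefined analyte {lab!r}"
                    )
        if self.terminal_rule not in ("after_tmax", "best_r2"):
            raise ConfigError(f"terminal_rule: unknown rule {self.terminal_rule!r}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sst_limits"] = dataclasses.asdict(self.sst_limits)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sst_limits" in d:
            d["sst_limits"] = SSTLimits(**d["sst_limits"])
        if "analytes" in d:
            d["analytes"] = {
                lab: AnalyteConfig(**{**a, "window": tuple(a["window"]),
                                      "calibration_levels": tuple(a.get("calibration_levels", ())),
                                      "qc_levels": tuple(a.get("qc_levels", ()))})
                for lab, a in d["analytes"].items()
            }
        for key in ("schedule",):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("stability", "degradation"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays vanilla."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def default_config(seed: int = 0) -> PipelineConfig:
    """The packaged study conditions.

    Analyte metadata mirrors the assay: retention times of the four
    peaks, the spiking levels of the calibration series, the published
    response lines as simulator ground truth, the QC levels, and the
    three patients' elimination constants / peak times / peak
    concentrations as ground truth for the plasma simulations.
    """
    analytes = {
        "CCA": AnalyteConfig(
            label="CCA", retention_time=9.663, window=(9.4, 9.95), lloq=0.01,
            calibration_levels=(0.015, 0.03, 0.06, 0.125, 0.5, 4.0),
            calibration_slope=0.2227, calibration_intercept=0.0158,
            qc_levels=(0.5, 1.0, 2.0, 4.0), qc_true_recovery=0.96, qc_cv=0.02,
        ),
        "ATV": AnalyteConfig(
            label="ATV", retention_time=10.998, window=(10.7, 11.3), lloq=0.005,
            calibration_levels=(0.005, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.28, 2.56),
            calibration_slope=0.3404, calibration_intercept=0.0017,
            qc_levels=(0.2, 0.3, 1.0, 2.5), qc_true_recovery=0.95, qc_cv=0.03,
            peak_tau=0.015,
        ),
        "IS": AnalyteConfig(label="IS", retention_time=11.802, window=(11.55, 12.1)),
        "CLP": AnalyteConfig(
            label="CLP", retention_time=12.682, window=(12.4, 13.0), lloq=0.008,
            calibration_levels=(0.008, 0.016, 0.032, 0.064, 0.128, 0.25, 0.5, 1.0, 2.0),
            calibration_slope=0.3789, calibration_intercept=0.0004,
            qc_levels=(0.25, 0.5, 1.0, 2.0), qc_true_recovery=0.96, qc_cv=0.03,
            peak_tau=0.055,
        ),
    }
    patients = {
        "patient1": {
            "CLP": {"ke": 0.81, "tmax": 0.25, "cmax": 0.10, "dose_mg": 75},
            "CCA": {"ke": 0.15, "tmax": 1.00, "cmax": 4.20, "dose_mg": 75},
            "ATV": {"ke": 0.08, "tmax": 3.00, "cmax": 0.09, "dose_mg": 20},
        },
        "patient2": {
            "CLP": {"ke": 0.58, "tmax": 0.25, "cmax": 0.08, "dose_mg": 75},
            "CCA": {"ke": 0.23, "tmax": 1.24, "cmax": 4.77, "dose_mg": 75},
            "ATV": {"ke": 0.08, "tmax": 2.52, "cmax": 0.15, "dose_mg": 40},
        },
        "patient3": {
            "CLP": {"ke": 1.02, "tmax": 0.25, "cmax": 0.07, "dose_mg": 75},
            "CCA": {"ke": 0.13, "tmax": 1.00, "cmax": 3.32, "dose_mg": 75},
            "ATV": {"ke": 0.07, "tmax": 3.06, "cmax": 0.19, "dose_mg": 80},
        },
    }
    stability = (
        {"analyte": "CCA", "condition": "short_term", "nominal": 0.12, "true_recovery": 0.92, "cv": 0.09},
        {"analyte": "CCA", "condition": "short_term", "nominal": 4.0, "true_recovery": 0.97, "cv": 0.04},
        {"analyte": "CCA", "condition": "long_term", "nominal": 0.12, "true_recovery": 0.92, "cv": 0.09},
        {"analyte": "CCA", "condition": "long_term", "nominal": 4.0, "true_recovery": 0.96, "cv": 0.02},
        {"analyte": "ATV", "condition": "short_term", "nominal": 0.5, "true_recovery": 0.94, "cv": 0.02},
        {"analyte": "ATV", "condition": "short_term", "nominal": 2.5, "true_recovery": 0.96, "cv": 0.01},
        {"analyte": "ATV", "condition": "long_term", "nominal": 0.5, "true_recovery": 0.92, "cv": 0.10},
        {"analyte": "ATV", "condition": "long_term", "nominal": 2.5, "true_recovery": 0.96, "cv": 0.01},
    )
    # stressed-to-reference peak fractions of the forced-degradation scenario
    degradation = (
        {"condition": "1M_HCl_3h_60C", "CLP": 0.62, "ATV": 0.89},
        {"condition": "1M_NaOH_3h_60C", "CLP": 0.70, "ATV": 0.73},
        {"condition": "5pct_H2O2_3h_60C", "CLP": 0.80, "ATV": 0.67},
    )
    cfg = PipelineConfig(
        seed=seed, analytes=analytes, patients=patients,
        stability=stability, degradation=degradation,
    )
    cfg.validate()
    return cfg


def _derive_seed(base: int, *tags: str) -> int:
    """Stable per-purpose integer seed below 2**31."""
    h = hashlib.sha256(("/".join((str(base),) + tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages

def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing stage inputs {missing} in {out}; run the simulate stage first"
        )


def stage_simulate(config: PipelineConfig, out: Path) -> None:
    """Generate every downstream input: chromatogram, calibration
    batches, QC replicate tables, stability sets, robustness retention
    times, and the patients' plasma profiles."""
    out.mkdir(parents=True, exist_ok=True)
    base = config.seed

    peaks = [
        PeakSpec(
            analyte_id=lab,
            retention_time=a.retention_time,
            area=config.peak_area,
            sigma=config.peak_sigma_min,
            tau=a.peak_tau,
        )
        for lab, a in config.analytes.items()
    ]
    chrom = generate_chromatogram(
        peaks,
        duration=config.duration_min,
        sampling_rate=config.sampling_rate_hz,
        baseline_noise_sd=config.baseline_noise_sd,
        seed=_derive_seed(base, "chromatogram"),
    )
    ckio.write_chromatogram(chrom, out / "chromatogram.tsv")
    log.info("simulate: chromatogram with %d points, %d peaks", len(chrom), len(peaks))

    is_area = 1.5e5  # fixed internal-standard response
    for lab, a in config.analytes.items():
        if not a.calibration_levels:
            continue
        rng = np.random.default_rng(_derive_seed(base, "calibration", lab))
        rows = []
        for conc in a.calibration_levels:
            ratio = a.calibration_slope * conc + a.calibration_intercept
            noise = np.exp(rng.normal(0.0, 0.002))
            rows.append((conc, ratio * is_area * noise, is_area))
        ckio.write_calibration_table(rows, lab, out / f"calibration_{lab}.tsv")

    qc_rows = []
    for lab, a in config.analytes.items():
        for period in ("intraday", "interday"):
            for nominal in a.qc_levels:
                cv = a.qc_cv * (2.0 if period == "interday" else 1.0)
                vals = generate_qc_replicates(
                    nominal, a.qc_true_recovery, cv, n=3,
                    seed=_derive_seed(base, "qc", lab, period, str(nominal)),
                )
                qc_rows += [
                    {"analyte_id": lab, "period": period, "nominal": nominal, "measured": v}
                    for v in vals
                ]
    ckio.write_qc_table(pd.DataFrame(qc_rows), out / "qc_replicates.tsv")
    log.info("simulate: %d QC replicate rows", len(qc_rows))

    stab_rows = []
    for spec in config.stability:
        vals = generate_qc_replicates(
            spec["nominal"], spec["true_recovery"], spec["cv"], n=3,
            seed=_derive_seed(base, "stability", spec["analyte"],
                              spec["condition"], str(spec["nominal"])),
        )
        stab_rows += [
            {"analyte_id": spec["analyte"], "period": spec["condition"],
             "nominal": spec["nominal"], "measured": v}
            for v in vals
        ]
    ckio.write_qc_table(pd.DataFrame(stab_rows), out / "stability_replicates.tsv")

    robust_rows = []
    for cond, shift in (("flow_0.9", +0.09), ("flow_1.0", 0.0), ("flow_1.1", -0.2),
                        ("pH_2.6", 0.0), ("pH_2.8", -0.05)):
        rng = np.random.default_rng(_derive_seed(base, "robustness", cond))
        for lab in ("CCA", "ATV", "CLP"):
            tr = config.analytes[lab].retention_time + shift
            for rep in rng.normal(tr, 0.02, size=6):
                robust_rows.append(
                    {"condition": cond, "analyte_id": lab, "tr_min": float(rep)}
                )
    pd.DataFrame(robust_rows).to_csv(
        out / "robustness_runs.tsv", sep="\t", index=False, float_format="%.6g"
    )

    for patient, per_analyte in config.patients.items():
        for lab, kin in per_analyte.items():
            ke, tmax, cmax = kin["ke"], kin["tmax"], kin["cmax"]
            ka = ka_from_tmax(ke, tmax)
            a_coef = cmax / (np.exp(-ke * tmax) - np.exp(-ka * tmax))
            params = BatemanParams(A=float(a_coef), Ka=ka, Ke=ke)
            schedule = SamplingSchedule(
                times=config.schedule,
                lloq=config.analytes[lab].lloq,
                noise_cv=config.noise_cv,
                seed=_derive_seed(base, "profile", patient, lab),
            )
            prof = generate_profile(
                params, schedule, analyte_id=lab, subject_id=patient,
                dose_mg=kin.get("dose_mg", 75.0),
            )
            ckio.write_profile(prof, out / f"profile_{patient}_{lab}.tsv")
    log.info("simulate: %d plasma profiles",
             sum(len(v) for v in config.patients.values()))


def stage_sst(config: PipelineConfig, out: Path) -> bool:
    """Detect the four assay peaks and evaluate system suitability."""
    _require(out, "chromatogram.tsv")
    chrom = ckio.read_chromatogram(out / "chromatogram.tsv")
    windows = {lab: a.window for lab, a in config.analytes.items()}
    try:
        peaks = detect_peaks(chrom, min_height=0.2, expected=windows)
    except ChromatographyError as exc:
        log.warning("sst: %s", exc)
        (out / "sst_report.tsv").write_text(f"# system suitability failed: {exc}\n")
        return False
    report = sst_evaluate(peaks, config.sst_limits)
    # S/N of the earliest peak against the early blank region
    try:
        snr = signal_to_noise(peaks[0], chrom, blank_region=(4.0, 8.0))
    except Exception:
        snr = float("nan")
    for row in report.rows:
        row["snr_first_blank"] = snr if row is report.rows[0] else None
    ckio.write_sst_report(report, out / "sst_report.tsv")
    log.info("sst: %d peaks, all_pass=%s", len(peaks), report.all_pass)
    return report.all_pass


def stage_calibrate(config: PipelineConfig, out: Path) -> bool:
    """Fit the IS-ratio calibration line for every calibrated analyte."""
    ok = True
    for lab, a in config.analytes.items():
        table = out / f"calibration_{lab}.tsv"
        if not table.exists():
            continue
        rows, analyte = ckio.read_calibration_table(table)
        curve = fit_calibration(rows, analyte_id=analyte)
        ckio.write_curve(curve, out / f"curve_{lab}.yaml")
        ok = ok and curve.r_squared > 0.99
        log.info("calibrate: %s slope=%.4f r2=%.5f", lab, curve.slope, curve.r_squared)
    return ok


def stage_validate(config: PipelineConfig, out: Path) -> bool:
    """Accuracy/precision, stability, robustness and degradation tables."""
    _require(out, "qc_replicates.tsv", "stability_replicates.tsv", "robustness_runs.tsv")
    qc = ckio.read_qc_table(out / "qc_replicates.tsv")
    rows = []
    for (lab, period, nominal), grp in qc.groupby(
        ["analyte_id", "period", "nominal"], sort=True
    ):
        rows.append(
            assess_qc(
                QCSet(
                    analyte_id=str(lab), period=str(period),
                    nominal=float(nominal),
                    measured=tuple(grp["measured"].astype(float)),
                )
            )
        )
    ckio.write_validation_report(rows, out / "validation_report.tsv")

    stab = ckio.read_qc_table(out / "stability_replicates.tsv")
    stab_rows = []
    for (lab, cond, nominal), grp in stab.groupby(
        ["analyte_id", "period", "nominal"], sort=True
    ):
        stab_rows.append(
            assess_stability(
                float(nominal), tuple(grp["measured"].astype(float)),
                condition=str(cond), analyte_id=str(lab),
            )
        )
    ckio.write_validation_report(stab_rows, out / "stability_report.tsv")

    robust = pd.read_csv(out / "robustness_runs.tsv", sep="\t")
    runs = [
        (str(cond), {
            str(lab): grp2["tr_min"].astype(float).tolist()
            for lab, grp2 in grp.groupby("analyte_id")
        })
        for cond, grp in robust.groupby("condition", sort=True)
    ]
    robustness_summary(runs).to_csv(
        out / "robustness_report.tsv", sep="\t", index=False, float_format="%.6g"
    )

    deg_rows = []
    reference_area = 1000.0
    for spec in config.degradation:
        for lab in ("CLP", "ATV"):
            deg_rows.append(
                {
                    "condition": spec["condition"],
                    "analyte_id": lab,
                    "recovery_pct": degradation_recovery(
                        reference_area, reference_area * spec[lab]
                    ),
                }
            )
    pd.DataFrame(deg_rows).to_csv(
        out / "degradation_report.tsv", sep="\t", index=False, float_format="%.6g"
    )
    all_pass = all(r.passed for r in rows) and all(r.passed for r in stab_rows)
    log.info("validate: %d QC rows, %d stability rows, all_pass=%s",
             len(rows), len(stab_rows), all_pass)
    return all_pass


def stage_pk(config: PipelineConfig, out: Path) -> bool:
    """Estimate the PK parameter set for every simulated profile."""
    results, failures = [], []
    pk_cfg = PKConfig(terminal_rule=config.terminal_rule)
    for path in sorted(out.glob("profile_*.tsv")):
        if path.name.endswith(".meta.yaml"):
            continue
        prof = ckio.read_profile(path)
        try:
            results.append(analyze_profile(prof, pk_cfg))
        except PKError as exc:
            failures.append(
                {"subject": prof.subject_id, "analyte": prof.analyte_id,
                 "error": str(exc)}
            )
    ckio.write_pk_report(results, out / "pk_report.tsv")
    if failures:
        pd.DataFrame(failures).to_csv(out / "pk_failures.tsv", sep="\t", index=False)
    log.info("pk: %d profiles analyzed, %d not estimable", len(results), len(failures))
    return len(results) > 0


def run_pipeline(
    config: PipelineConfig,
    stage: str = "all",
    out_dir: str | Path = "results/pipeline",
    seed: int | None = None,
) -> int:
    """Run one stage (or all) and write reports plus a run manifest.

    Returns 0 when every report's acceptance flags pass, 1 when any
    report flags a failure. Invalid configs raise :class:`ConfigError`.
    """
    if stage not in STAGES:
        raise ConfigError(f"stage: unknown stage {stage!r}")
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages = ("simulate", "sst", "calibrate", "validate", "pk") if stage == "all" else (stage,)
    ok = True
    for s in stages:
        if s == "simulate":
            stage_simulate(config, out)
        elif s == "sst":
            ok = stage_sst(config, out) and ok
        elif s == "calibrate":
            ok = stage_calibrate(config, out) and ok
        elif s == "validate":
            ok = stage_validate(config, out) and ok
        elif s == "pk":
            ok = stage_pk(config, out) and ok

    import chromapk

    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "version": chromapk.__version__,
        "stages": list(stages),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return 0 if ok else 1
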