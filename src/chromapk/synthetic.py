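"""Seeded generators for every input the pipeline consumes.

The module produces multi-peak UV chromatograms, internal-standard
calibration batches, QC replicate sets, and Bateman-shaped plasma
concentration-time profiles with known ground truth, so the whole
pipeline runs without instrument data.

Conventions
-----------
* Chromatogram time is in minutes; peak areas are in signal*seconds
  (detector response integrated over time), so the generator deposits
  ``area / 60`` per unit minute.
* Concentration noise is multiplicative lognormal with unit mean
  (concentrations stay positive, CV is exact); chromatogram baseline
  noise is additive Gaussian.
* Every stochastic call takes one explicit integer seed; there is no
  global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from chromapk.chromatography import Chromatogram
from chromapk.pk import ConcentrationTimeProfile

__all__ = [
    "PeakSpec",
    "BatemanParams",
    "SamplingSchedule",
    "bateman_concentration",
    "generate_profile",
    "generate_chromatogram",
    "generate_qc_replicates",
    "default_peaks",
    "DEFAULT_RETENTION_TIMES",
    "DEFAULT_SCHEDULE_HOURS",
]

#: Retention times (min) of the four assay peaks in elution order:
#: clopidogrel carboxylic acid metabolite, atorvastatin, ibuprofen (IS),
#: clopidogrel.
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "CCA": 9.663,
    "ATV": 10.998,
    "IS": 11.802,
    "CLP": 12.682,
}

#: Plasma sampling times (h) of the in-vivo study design: a pre-dose
#: sample plus 0.25, 0.5, 1, 3, 6, 9 and 12 h post dose.
DEFAULT_SCHEDULE_HOURS: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 3.0, 6.0, 9.0, 12.0)


@dataclass(frozen=True)
class PeakSpec:
    """One simulated chromatographic peak.

    ``retention_time`` is the center of the Gaussian component (min);
    a positive ``tau`` adds an exponential tail (EMG shape), which
    shifts the apex slightly later and raises the tailing factor.
    ``area`` is the integrated response in signal*seconds.
    """

    analyte_id: str
    retention_time: float
    area: float
    sigma: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError("retention_time must be > 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class BatemanParams:
    """One-compartment oral model parameters.

    ``A`` is the pre-exponential coefficient F*D*Ka / (V*(Ka - Ke)) in
    ug/mL; ``Ka`` and ``Ke`` are the first-order absorption and
    elimination rate constants in 1/h. The degenerate case Ka == Ke has
    a different functional form and is rejected.
    """

    A: float
    Ka: float
    Ke: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be > 0")
        if self.Ka <= 0 or self.Ke <= 0:
            raise ValueError("rate constants must be > 0")
        if self.Ka == self.Ke:
            raise ValueError(
                "Ka == Ke is outside the Bateman form; the limiting model "
                "A*Ke*t*exp(-Ke*t) is not implemented"
            )

    @property
    def tmax(self) -> float:
        """Time of the curve maximum, ln(Ka/Ke)/(Ka - Ke)."""
        return float(np.log(self.Ka / self.Ke) / (self.Ka - self.Ke))

    @property
    def cmax(self) -> float:
        """Concentration at :attr:`tmax`."""
        return bateman_concentration(self, self.tmax)

    @property
    def auc_inf(self) -> float:
        """Analytic total exposure A*(1/Ke - 1/Ka)."""
        return self.A * (1.0 / self.Ke - 1.0 / self.Ka)


@dataclass(frozen=True)
class SamplingSchedule:
    """Plasma sampling design: times (h), quantification limit and noise."""

    times: tuple[float, ...] = DEFAULT_SCHEDULE_HOURS
    lloq: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.lloq < 0:
            raise ValueError("lloq must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        object.__setattr__(self, "times", tuple(float(x) for x in t))


def bateman_concentration(params: BatemanParams, t) -> np.ndarray | float:
    """Plasma concentration of the one-compartment oral model.

    Cp(t) = A * (exp(-Ke*t) - exp(-Ka*t)); vectorized over ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    c = params.A * (np.exp(-params.Ke * t_arr) - np.exp(-params.Ka * t_arr))
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(n)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=n)


def generate_profile(
    params: BatemanParams,
    schedule: SamplingSchedule,
    analyte_id: str = "CCA",
    subject_id: str = "sim",
    dose_mg: float = 75.0,
) -> ConcentrationTimeProfile:
    """Sample a Bateman curve on ``schedule`` with lognormal assay noise.

    Concentrations below the LLOQ are kept in the record but flagged
    censored; downstream fits and trapezoids skip them. The ground-truth
    parameters are attached for recovery studies.
    """
    times = np.asarray(schedule.times, dtype=float)
    rng = np.random.default_rng(schedule.seed)
    clean = np.asarray(bateman_concentration(params, times), dtype=float)
    conc = clean * _lognormal_factors(rng, schedule.noise_cv, times.size)
    censored = conc < schedule.lloq
    return ConcentrationTimeProfile(
        analyte_id=analyte_id,
        subject_id=subject_id,
        dose_mg=dose_mg,
        times=tuple(times),
        concentrations=tuple(conc),
        censored=tuple(bool(c) for c in censored),
        lloq=schedule.lloq,
        truth=params,
    )


def _peak_signal(peak: PeakSpec, time_min: np.ndarray) -> np.ndarray:
    # area is in signal*seconds while the axis is minutes: 60 s/min.
    area_per_min = peak.area / 60.0
    if peak.tau == 0:
        return area_per_min * stats.norm.pdf(
            time_min, loc=peak.retention_time, scale=peak.sigma
        )
    k = peak.tau / peak.sigma
    return area_per_min * stats.exponnorm.pdf(
        time_min, K=k, loc=peak.retention_time, scale=peak.sigma
    )


def generate_chromatogram(
    peaks: Sequence[PeakSpec],
    duration: float = 20.0,
    sampling_rate: float = 10.0,
    baseline_noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Sum of Gaussian/EMG peaks plus additive Gaussian baseline noise.

    ``sampling_rate`` is in Hz (points per second), matching detector
    conventions; ``duration`` is the run length in minutes. Each peak's
    integrated area converges to its specified area as noise goes to zero.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    for p in peaks:
        if not (0.0 < p.retention_time < duration):
            raise ValueError(
                f"peak {p.analyte_id!r} at {p.retention_time} min lies outside "
                f"the 0-{duration} min run"
            )
    n = int(round(duration * 60.0 * sampling_rate)) + 1
    time_min = np.linspace(0.0, duration, n)
    signal = np.zeros(n)
    for p in peaks:
        signal += _peak_signal(p, time_min)
    if baseline_noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, baseline_noise_sd, size=n)
    return Chromatogram(time=time_min, signal=signal)


def generate_qc_replicates(
    nominal: float,
    true_recovery: float,
    cv: float,
    n: int,
    seed: int = 0,
) -> list[float]:
    """``n`` measured concentrations around ``nominal * true_recovery``.

    Emulates replicate QC analysis: the true assay bias sets the center,
    the CV sets the spread (unit-mean lognormal, so cv=0 reproduces the
    center exactly).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    center = nominal * true_recovery
    return [float(v) for v in center * _lognormal_factors(rng, cv, n)]


def default_peaks(
    total_area: float = 50.0,
    sigma: float = 0.05,
    tailed: bool = False,
) -> list[PeakSpec]:
    """The four assay peaks at their nominal retention times.

    With ``tailed=True`` the clopidogrel peak gets an exponential tail
    (tau chosen to push its tailing factor toward ~1.5) so the SST code
    paths for asymmetric peaks are exercised.
    """
    taus = {"CCA": 0.0, "ATV": 0.0, "IS": 0.0, "CLP": 0.0}
    if tailed:
        taus["ATV"] = 0.3 * sigma
        taus["CLP"] = 1.1 * sigma
    return [
        PeakSpec(
            analyte_id=name,
            retention_time=rt,
            area=total_area,
            sigma=sigma,
            tau=taus[name],
        )
        for name, rt in DEFAULT_RETENTION_TIMES.items()
    ]
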