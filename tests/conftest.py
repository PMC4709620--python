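import numpy as np
import pytest

from chromapk.synthetic import (
    BatemanParams,
    PeakSpec,
    SamplingSchedule,
    generate_chromatogram,
)

STUDY_SCHEDULE = (0.0, 0.25, 0.5, 1.0, 3.0, 6.0, 9.0, 12.0)


@pytest.fixture
def reference_bateman() -> BatemanParams:
    """Metabolite-scale kinetics: slow elimination, ten-fold faster absorption."""
    return BatemanParams(A=10.0, Ka=1.5, Ke=0.15)


@pytest.fixture
def noiseless_schedule() -> SamplingSchedule:
    return SamplingSchedule(times=STUDY_SCHEDULE, lloq=0.0, noise_cv=0.0, seed=0)


@pytest.fixture
def single_gaussian_chrom():
    """One symmetric peak: tR 10 min, sigma 0.1 min, area 5 signal*s."""
    peak = PeakSpec(analyte_id="X", retention_time=10.0, area=5.0, sigma=0.1)
    return peak, generate_chromatogram([peak], duration=20.0, sampling_rate=10.0)


@pytest.fixture
def four_peak_chrom():
    """The four assay peaks at their nominal retention times, no noise."""
    peaks = [
        PeakSpec("CCA", 9.663, 50.0, 0.05),
        PeakSpec("ATV", 10.998, 50.0, 0.05),
        PeakSpec("IS", 11.802, 50.0, 0.05),
        PeakSpec("CLP", 12.682, 50.0, 0.05),
    ]
    return peaks, generate_chromatogram(peaks, duration=20.0, sampling_rate=10.0)


def gaussian_width_at_half(sigma: float) -> float:
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
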