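"""Peak measurement and system-suitability metrics against Gaussian closed forms."""

import numpy as np
import pytest

from chromapk.chromatography import (
    Chromatogram,
    CoElutionWarning,
    PeakMeasurement,
    SSTLimits,
    UndefinedSNRError,
    detect_peaks,
    plate_count,
    resolution,
    signal_to_noise,
    sst_evaluate,
    tailing_factor,
    MissingAnalyteError,
)
from chromapk.synthetic import PeakSpec, generate_chromatogram

from conftest import gaussian_width_at_half


def symmetric_measurement(tr=10.0, sigma=0.1, height=1.0):
    w50 = gaussian_width_at_half(sigma)
    # 5% width of a Gaussian: 2*sigma*sqrt(2*ln20)
    w5 = 2.0 * sigma * np.sqrt(2.0 * np.log(20.0))
    return PeakMeasurement(
        analyte_id="X", retention_time=tr, area=1.0, height=height,
        width_at_half=w50, width_at_5pct=w5, front_at_5pct=w5 / 2.0,
    )


class TestDetectPeaks:
    def test_single_gaussian_round_trip(self, single_gaussian_chrom):
        peak, chrom = single_gaussian_chrom
        found = detect_peaks(chrom, min_height=0.05)
        assert len(found) == 1
        m = found[0]
        assert m.retention_time == pytest.approx(10.0, abs=0.005)
        assert m.area == pytest.approx(5.0, rel=5e-3)

    def test_flat_trace_yields_nothing(self):
        chrom = Chromatogram(time=np.linspace(0, 20, 1000), signal=np.zeros(1000))
        assert detect_peaks(chrom, min_height=0.1) == []

    def test_elution_order_preserved(self, four_peak_chrom):
        _, chrom = four_peak_chrom
        windows = {
            "CLP": (12.4, 13.0), "CCA": (9.4, 9.9),
            "IS": (11.6, 12.0), "ATV": (10.7, 11.3),
        }
        found = detect_peaks(chrom, min_height=1.0, expected=windows)
        assert [m.analyte_id for m in found] == ["CCA", "ATV", "IS", "CLP"]

    def test_missing_analyte_raises(self, four_peak_chrom):
        _, chrom = four_peak_chrom
        with pytest.raises(MissingAnalyteError, match="GHOST"):
            detect_peaks(chrom, min_height=1.0, expected={"GHOST": (2.0, 3.0)})

    def test_uniform_offset_invariance(self, single_gaussian_chrom):
        peak, chrom = single_gaussian_chrom
        shifted = Chromatogram(time=chrom.time, signal=chrom.signal + 3.7)
        m0 = detect_peaks(chrom, min_height=0.05)[0]
        m1 = detect_peaks(shifted, min_height=0.05)[0]
        assert m1.area == pytest.approx(m0.area, rel=1e-6)
        assert m1.height == pytest.approx(m0.height, rel=1e-6)

    def test_area_additivity_of_separated_peaks(self):
        p1 = PeakSpec("A", 8.0, 3.0, 0.05)
        p2 = PeakSpec("B", 14.0, 7.0, 0.05)
        both = detect_peaks(
            generate_chromatogram([p1, p2], 20.0, 10.0), min_height=0.2
        )
        singles = [
            detect_peaks(generate_chromatogram([p], 20.0, 10.0), min_height=0.2)[0]
            for p in (p1, p2)
        ]
        total_both = sum(m.area for m in both)
        total_single = sum(m.area for m in singles)
        assert total_both == pytest.approx(total_single, rel=2e-3)


class TestPlateCount:
    def test_gaussian_closed_form(self):
        m = symmetric_measurement(tr=10.0, sigma=0.1)
        assert plate_count(m) == pytest.approx(9989.0, rel=0.01)

    def test_direct_formula(self):
        m = symmetric_measurement()
        m = PeakMeasurement(
            "X", 10.0, 1.0, 1.0, 10.0 / np.sqrt(5.54), m.width_at_5pct, m.front_at_5pct
        )
        assert plate_count(m) == pytest.approx(30.6916, abs=1e-10)

    @pytest.mark.parametrize("sigma", [0.02, 0.05, 0.1, 0.2])
    def test_measured_gaussian_matches_closed_form(self, sigma):
        chrom = generate_chromatogram(
            [PeakSpec("X", 10.0, 5.0, sigma)], duration=20.0, sampling_rate=20.0
        )
        m = detect_peaks(chrom, min_height=0.01)[0]
        expected = 5.54 * (10.0 / gaussian_width_at_half(sigma)) ** 2
        assert plate_count(m) == pytest.approx(expected, rel=0.01)


class TestTailingFactor:
    def test_symmetric_peak_is_unity(self, single_gaussian_chrom):
        _, chrom = single_gaussian_chrom
        m = detect_peaks(chrom, min_height=0.05)[0]
        assert tailing_factor(m) == pytest.approx(1.0, abs=0.01)

    def test_moderate_tail_passes_limit(self):
        chrom = generate_chromatogram(
            [PeakSpec("CLP", 12.682, 50.0, 0.05, tau=0.055)], 20.0, 20.0
        )
        m = detect_peaks(chrom, min_height=1.0)[0]
        t = tailing_factor(m)
        assert 1.2 < t <= 2.0
        report = sst_evaluate([m])
        assert report.rows[0]["tailing_pass"]

    def test_heavy_tail_fails_limit(self):
        chrom = generate_chromatogram(
            [PeakSpec("X", 10.0, 50.0, 0.05, tau=0.5)], 20.0, 20.0
        )
        m = detect_peaks(chrom, min_height=0.5)[0]
        assert tailing_factor(m) > 2.0
        assert not sst_evaluate([m]).rows[0]["tailing_pass"]


class TestResolution:
    def test_gaussian_pair_closed_form(self):
        # two sigma=0.1 peaks 1 min apart: Wb = 0.4 each, Rs = 2*1/0.8 = 2.5
        m1 = symmetric_measurement(tr=10.0, sigma=0.1)
        m2 = symmetric_measurement(tr=11.0, sigma=0.1)
        assert resolution(m1, m2) == pytest.approx(2.5, rel=0.02)

    def test_coelution_warns_and_returns_zero(self):
        m = symmetric_measurement()
        with pytest.warns(CoElutionWarning):
            assert resolution(m, m) == 0.0

    def test_monotone_in_separation(self):
        m1 = symmetric_measurement(tr=10.0)
        rs = [resolution(m1, symmetric_measurement(tr=10.0 + d)) for d in (0.5, 1.0, 2.0)]
        assert rs == sorted(rs)


class TestSignalToNoise:
    def _noisy_chrom(self, height):
        peak = PeakSpec("X", 10.0, height * 0.1 * np.sqrt(2 * np.pi) * 60, 0.1)
        return generate_chromatogram(
            [peak], 20.0, 10.0, baseline_noise_sd=0.01, seed=5
        )

    def test_scales_linearly_with_height(self):
        c1, c2 = self._noisy_chrom(1.0), self._noisy_chrom(2.0)
        m1 = detect_peaks(c1, min_height=0.5)[0]
        m2 = detect_peaks(c2, min_height=0.5)[0]
        blank = (2.0, 6.0)
        ratio = signal_to_noise(m2, c2, blank) / signal_to_noise(m1, c1, blank)
        assert ratio == pytest.approx(m2.height / m1.height, rel=0.01)

    def test_constructed_three_to_one(self):
        chrom = self._noisy_chrom(1.0)
        m = detect_peaks(chrom, min_height=0.5)[0]
        # measure the blank excursion, then scale a peak to 1.5x of it
        from scipy.signal import detrend

        mask = (chrom.time >= 2.0) & (chrom.time <= 6.0)
        ptp = float(np.ptp(detrend(chrom.signal[mask])))
        m3 = PeakMeasurement(
            "X", m.retention_time, m.area, 1.5 * ptp,
            m.width_at_half, m.width_at_5pct, m.front_at_5pct,
        )
        assert signal_to_noise(m3, chrom, (2.0, 6.0)) == pytest.approx(3.0, rel=1e-9)

    def test_noiseless_blank_is_an_error(self, single_gaussian_chrom):
        _, chrom = single_gaussian_chrom
        m = detect_peaks(chrom, min_height=0.05)[0]
        with pytest.raises(UndefinedSNRError):
            signal_to_noise(m, chrom, (2.0, 6.0))


class TestSSTEvaluate:
    def test_default_scenario_all_pass(self, four_peak_chrom):
        _, chrom = four_peak_chrom
        report = sst_evaluate(detect_peaks(chrom, min_height=1.0))
        assert report.all_pass
        assert report.rows[0]["resolution"] is None
        assert all(r["resolution"] > 2.0 for r in report.rows[1:])

    def test_single_peak_report_omits_resolution(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            report = sst_evaluate([symmetric_measurement()])
        assert report.rows[0]["resolution"] is None
        assert report.all_pass

    def test_boundary_semantics(self):
        # plate count strictly above its limit: N exactly at the limit fails
        m = symmetric_measurement()
        n_exact = plate_count(m)
        row = sst_evaluate([m], SSTLimits(plate_count_min=n_exact)).rows[0]
        assert not row["plate_count_pass"]
        # tailing inclusive: T exactly at the limit passes; front exactly a
        # quarter of the 5% width gives T = 2.0
        w5 = m.width_at_5pct
        t_at_limit = PeakMeasurement(
            "X", 10.0, 1.0, 1.0, m.width_at_half, w5, w5 / 4.0
        )
        assert tailing_factor(t_at_limit) == pytest.approx(2.0, abs=1e-12)
        assert sst_evaluate([t_at_limit]).rows[0]["tailing_pass"]

    def test_unordered_peaks_rejected(self):
        m1 = symmetric_measurement(tr=10.0)
        m2 = symmetric_measurement(tr=11.0)
        with pytest.raises(ValueError, match="ordered"):
            sst_evaluate([m2, m1])
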