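"""Terminal-slope, feathering and AUC estimation against analytic oracles."""

import numpy as np
import pytest

from chromapk.pk import (
    ConcentrationTimeProfile,
    EligibilityError,
    ModelViolationError,
    NoEliminationPhaseError,
    PKConfig,
    PKStageError,
    TerminalFit,
    analyze_profile,
    auc_to_infinity,
    auc_trapezoid,
    half_life,
    method_of_residuals,
    terminal_ke,
    tmax_model,
)
from chromapk.synthetic import (
    BatemanParams,
    SamplingSchedule,
    bateman_concentration,
    generate_profile,
)

from conftest import STUDY_SCHEDULE


def monoexp_profile(c0=10.0, ke=0.2, times=(3.0, 6.0, 9.0, 12.0)):
    conc = tuple(c0 * np.exp(-ke * t) for t in times)
    return ConcentrationTimeProfile("X", "s", 75.0, times, conc)


class TestTerminalKe:
    def test_exact_monoexponential(self):
        fit = terminal_ke(monoexp_profile(), candidate_points=(3.0, 6.0, 9.0, 12.0))
        assert fit.ke == pytest.approx(0.2, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_concentration_rejected(self):
        prof = ConcentrationTimeProfile(
            "X", "s", 75.0, (1.0, 2.0, 3.0, 4.0), (5.0, 5.0, 5.0, 5.0)
        )
        with pytest.raises(NoEliminationPhaseError):
            terminal_ke(prof, candidate_points=(1.0, 2.0, 3.0, 4.0))

    def test_bateman_terminal_window(self, reference_bateman, noiseless_schedule):
        prof = generate_profile(reference_bateman, noiseless_schedule)
        fit = terminal_ke(prof, candidate_points=(6.0, 9.0, 12.0))
        assert fit.ke == pytest.approx(0.15, rel=0.01)

    def test_too_few_points_rejected(self):
        prof = monoexp_profile(times=(3.0, 6.0))
        with pytest.raises(EligibilityError):
            terminal_ke(prof, candidate_points=(3.0, 6.0))


class TestMethodOfResiduals:
    def test_exact_terminal_line_recovers_ka(self, reference_bateman, noiseless_schedule):
        p = reference_bateman
        prof = generate_profile(p, noiseless_schedule)
        exact = TerminalFit(
            ke=p.Ke, slope=-p.Ke / np.log(10), intercept=np.log10(p.A),
            r_squared=1.0, n_points=3, times=(6.0, 9.0, 12.0),
        )
        ka = method_of_residuals(prof, exact, absorption_times=(0.25, 0.5, 1.0))
        assert ka == pytest.approx(1.5, rel=0.02)

    def test_monoexponential_has_no_absorption_phase(self):
        prof = monoexp_profile(times=(0.5, 1.0, 3.0, 6.0, 9.0, 12.0))
        fit = terminal_ke(prof, candidate_points=(3.0, 6.0, 9.0, 12.0))
        with pytest.raises(ModelViolationError):
            method_of_residuals(prof, fit, absorption_times=(0.5, 1.0))

    def test_ka_ordering_preserved(self, noiseless_schedule):
        kas = []
        for ratio in (10.0, 20.0):
            p = BatemanParams(A=10.0, Ka=0.15 * ratio, Ke=0.15)
            prof = generate_profile(p, noiseless_schedule)
            fit = terminal_ke(prof, candidate_points=(6.0, 9.0, 12.0))
            kas.append(method_of_residuals(prof, fit))
        assert kas[0] < kas[1]


class TestDerivedParameters:
    def test_half_life_identity(self):
        assert half_life(np.log(2.0)) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("ke,expected", [(0.58, 1.20), (1.02, 0.68), (0.23, 3.01)])
    def test_half_life_clinical_magnitudes(self, ke, expected):
        assert round(half_life(ke), 2) == expected

    def test_tmax_closed_form(self):
        assert tmax_model(np.e, 1.0) == pytest.approx(0.5819767068693265, abs=1e-12)

    def test_tmax_near_degenerate_limit(self):
        ke = 0.5
        assert tmax_model(ke * (1 + 1e-6), ke) == pytest.approx(1 / ke, abs=1e-4)

    def test_tmax_degenerate_rejected(self):
        with pytest.raises(ValueError):
            tmax_model(0.5, 0.5)

    def test_curve_flat_at_tmax(self, reference_bateman):
        t = tmax_model(reference_bateman.Ka, reference_bateman.Ke)
        h = 1e-5
        d = (
            bateman_concentration(reference_bateman, t + h)
            - bateman_concentration(reference_bateman, t - h)
        ) / (2 * h)
        assert abs(d) < 1e-6


class TestAUC:
    def test_single_trapezoid(self):
        prof = ConcentrationTimeProfile("X", "s", 75.0, (0.0, 1.0), (0.0, 2.0))
        assert auc_trapezoid(prof) == pytest.approx(1.0)

    def test_fine_grid_exponential(self):
        t = np.arange(0.0, 10.0 + 1e-9, 0.001)
        prof = ConcentrationTimeProfile("X", "s", 75.0, tuple(t), tuple(np.exp(-t)))
        assert auc_trapezoid(prof) == pytest.approx(1.0 - np.exp(-10.0), abs=1e-5)

    def test_halving_step_reduces_error(self, reference_bateman):
        exact = reference_bateman.auc_inf - (
            reference_bateman.A / reference_bateman.Ke * np.exp(-reference_bateman.Ke * 12)
            - reference_bateman.A / reference_bateman.Ka * np.exp(-reference_bateman.Ka * 12)
        )
        errs = []
        for dt in (0.5, 0.25):
            t = np.arange(0.0, 12.0 + 1e-9, dt)
            c = bateman_concentration(reference_bateman, t)
            prof = ConcentrationTimeProfile("X", "s", 75.0, tuple(t), tuple(c))
            errs.append(abs(auc_trapezoid(prof) - exact))
        assert errs[1] < errs[0] / 2.0

    def test_censored_points_excluded(self):
        prof = ConcentrationTimeProfile(
            "X", "s", 75.0, (0.0, 1.0, 2.0), (0.0, 2.0, 2.0),
            censored=(False, False, True),
        )
        assert auc_trapezoid(prof) == pytest.approx(1.0)

    def test_infinity_extrapolation_algebra(self):
        assert auc_to_infinity(17.79, 0.4005, 0.15) == pytest.approx(20.46, abs=1e-12)
        assert auc_to_infinity(5.0, 0.0, 0.3) == 5.0
        assert auc_to_infinity(5.0, 1.0, 0.3) >= 5.0


class TestAnalyzeProfile:
    def test_noiseless_recovery(self, reference_bateman, noiseless_schedule):
        prof = generate_profile(reference_bateman, noiseless_schedule)
        res = analyze_profile(prof, PKConfig(terminal_rule="best_r2"))
        assert res.ke == pytest.approx(0.15, rel=0.01)
        assert res.ka == pytest.approx(1.5, rel=0.05)
        assert res.auc_0_inf == pytest.approx(reference_bateman.auc_inf, rel=0.03)
        assert res.t_half * res.ke == pytest.approx(np.log(2.0), abs=1e-12)
        assert res.tmax_model == pytest.approx(
            np.log(res.ka / res.ke) / (res.ka - res.ke), abs=1e-12
        )
        assert res.auc_0_inf >= res.auc_0_t

    def test_fully_censored_profile_rejected(self, reference_bateman):
        sched = SamplingSchedule(times=STUDY_SCHEDULE, lloq=1e6, noise_cv=0.0)
        prof = generate_profile(reference_bateman, sched)
        with pytest.raises(EligibilityError):
            analyze_profile(prof)

    @pytest.mark.parametrize("seed", [101, 202])
    def test_noisy_recovery_within_stochastic_tolerance(self, reference_bateman, seed):
        sched = SamplingSchedule(times=STUDY_SCHEDULE, lloq=0.0, noise_cv=0.05, seed=seed)
        prof = generate_profile(reference_bateman, sched)
        res = analyze_profile(prof, PKConfig(terminal_rule="best_r2"))
        assert res.ke == pytest.approx(0.15, rel=0.10)

    def test_flip_flop_reports_larger_rate_as_ka(self):
        # constructed so the feathering residuals decay slower than the
        # terminal line: the rate roles cannot be resolved and the larger
        # rate must be reported as Ka, with the flag raised
        times = (0.0, 1.0, 2.0, 3.0, 4.0)
        ext = 10.0 * np.exp(-np.array(times))
        resid = np.array([0.5, 0.4, 0.0, 0.0, 0.0])
        conc = tuple(ext - resid)
        prof = ConcentrationTimeProfile("X", "s", 75.0, times, conc)
        res = analyze_profile(
            prof,
            PKConfig(terminal_times=(2.0, 3.0, 4.0), absorption_times=(0.0, 1.0)),
        )
        assert res.flip_flop_flag
        assert res.ka >= res.ke
        assert res.ka == pytest.approx(1.0, rel=1e-6)
        assert res.ke == pytest.approx(np.log(0.5 / 0.4), rel=1e-6)

    def test_stage_label_on_component_failure(self):
        prof = monoexp_profile(times=(1.0, 2.0, 3.0, 6.0, 9.0))
        with pytest.raises(PKStageError, match="method_of_residuals"):
            analyze_profile(prof)
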