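"""Elongation-rate estimators: model fit, total runoff time, initiation rate."""

import numpy as np
import pytest

import ribotrace as rt
from ribotrace.estimators import (
    disappearance_times,
    elongation_from_runoff_time,
    estimate_initiation_rate,
    fit_runoff_elongation,
    runoff_model_curve,
)


@pytest.fixture(scope="module")
def ideal_curve(kif):
    times = np.arange(-150.0, 2400.0, 30.0)
    green = runoff_model_curve(times, 3.5, kif, t0=60.0)
    return rt.IntensityTrace("ideal", times, green, np.zeros_like(times), 30.0)


class TestRunoffModelCurve:
    def test_three_stages(self, kif):
        t = np.array([-30.0, 0.0, 30.0, 250.0, 500.0])
        y = runoff_model_curve(t, 3.5, kif, t0=0.0)
        assert y[0] == 1.0 and y[1] == 1.0
        assert 0 < y[3] < y[2] < 1.0
        assert y[4] == 0.0  # past L/k = 419 s

    def test_stage2_normalized_slope(self, kif):
        """In the linear stage the normalized slope is -k / (L c_bar)."""
        k = 3.5
        a, b, L = kif.first_visible_codon, kif.last_visible_codon, kif.orf_length_codons
        cbar = ((b - a) / 2 + (L - b)) / L  # ramp-model c_bar = 0.751
        t = np.array([250.0, 300.0])  # inside stage 2 (b/k=191 .. L/k=419)
        y = runoff_model_curve(t, k, kif, t0=0.0)
        slope = (y[1] - y[0]) / 50.0
        assert slope == pytest.approx(-k / (L * cbar), rel=1e-9)
        assert slope == pytest.approx(-3.17e-3, rel=0.01)

    def test_fit_self_consistency(self, kif, ideal_curve):
        fit = fit_runoff_elongation([ideal_curve], kif, n_bootstrap=0)
        assert fit.ok
        assert fit.rate_codons_per_s == pytest.approx(3.5, abs=1e-3)

    def test_no_decay_flagged_not_raised(self, kif):
        times = np.arange(-60.0, 1200.0, 30.0)
        green = np.full_like(times, 12.0)
        tr = rt.IntensityTrace("flat", times, green, np.zeros_like(times), 30.0)
        fit = fit_runoff_elongation([tr], kif, n_bootstrap=0)
        assert not fit.ok and np.isnan(fit.rate_codons_per_s)

    def test_mismatched_grids_rejected(self, kif, ideal_curve):
        other = rt.IntensityTrace(
            "other", ideal_curve.times + 5.0, ideal_curve.green,
            ideal_curve.red, 30.0,
        )
        with pytest.raises(ValueError):
            fit_runoff_elongation([ideal_curve, other], kif)

    def test_stochastic_ensemble_recovery(self, runoff_ensemble_35, kif):
        fit = fit_runoff_elongation(runoff_ensemble_35, kif, n_bootstrap=50, seed=1)
        assert fit.rate_codons_per_s == pytest.approx(3.5, abs=0.3)
        assert fit.sd > 0
        lo, hi = fit.stage_boundaries_s
        assert 0 < lo < hi

    def test_two_estimators_agree_on_same_ensemble(self, runoff_ensemble_35, kif):
        """Model fit and total-runoff-time agree within joint uncertainty."""
        fit_model = fit_runoff_elongation(runoff_ensemble_35, kif, n_bootstrap=50, seed=2)
        fit_time = elongation_from_runoff_time(
            disappearance_times(runoff_ensemble_35), kif
        )
        joint = 2 * np.hypot(fit_model.sd, fit_time.sd) + 0.25  # small-model-mismatch slack
        assert abs(fit_model.rate_codons_per_s - fit_time.rate_codons_per_s) <= joint


class TestRunoffTimeEstimator:
    def test_reference_times(self, kif):
        fit = elongation_from_runoff_time([480.0, 520.0, 560.0], kif, entry_delay_s=60)
        assert fit.rate_codons_per_s == pytest.approx(1467 / 460, rel=1e-9)
        assert fit.sd > 0

    def test_single_time_inverse_identity(self, kif):
        for k_star in (2.0, 3.1, 4.9):
            fit = elongation_from_runoff_time([1467 / k_star + 60.0], kif)
            assert fit.rate_codons_per_s == pytest.approx(k_star, rel=1e-12)

    def test_errors(self, kif):
        with pytest.raises(ValueError):
            elongation_from_runoff_time([], kif)
        with pytest.raises(ValueError):
            elongation_from_runoff_time([50.0, 500.0], kif, entry_delay_s=60)

    def test_simulated_recovery_at_3p1(self, kif):
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.1)
        traces = rt.simulate_runoff_ensemble(
            kif, kin, 100, rt.DrugEvent("harringtonine"), seed=61
        )
        fit = elongation_from_runoff_time(disappearance_times(traces), kif)
        assert 2.9 <= fit.rate_codons_per_s <= 3.3


class TestInitiationRate:
    @pytest.mark.parametrize(
        "n, k, expected",
        [(10, 3.5, 1.43), (25, 3.5, 3.58), (0, 3.5, 0.0)],
    )
    def test_flux_balance(self, kif, n, k, expected):
        assert estimate_initiation_rate(n, k, kif) == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs(self, kif):
        with pytest.raises(ValueError):
            estimate_initiation_rate(float("inf"), 3.5, kif)
        with pytest.raises(ValueError):
            estimate_initiation_rate(10, 0.0, kif)
        with pytest.raises(ValueError):
            estimate_initiation_rate(-1, 3.5, kif)
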