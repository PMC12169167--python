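import numpy as np
import pytest
from scipy.optimize import brentq

from helpers import dense_slope_oracle, run_trial
from tendonmech.mechanics import ForceTrace
from tendonmech.stiffness import (
    ForceElongationTrial,
    MeanCurve,
    common_force,
    fit_trial,
    mean_curve,
    pair_force_elongation,
    stiffness_slope,
)
from tendonmech.tracking import ElongationSeries


def _analytic_trial(a=200.0, b=500.0, peak=4000.0, n=100, noise_sd=0.0, seed=0):
    """(F, e) pairs lying on F = a e^2 + b e, optionally with elongation noise.

    Pairs sit exactly on the 100-point resampling grid so that a noise-free
    trial round-trips through the fit without interpolation error.
    """
    rng = np.random.default_rng(seed)
    f = np.linspace(0.0, peak, n)
    e = f / b if a == 0 else (-b + np.sqrt(b * b + 4 * a * f)) / (2 * a)
    e = e + rng.normal(0, noise_sd, size=n)
    return ForceElongationTrial(force=f, elongation=e)


class TestPairing:
    def test_identity_pairing_at_equal_rates(self):
        force = ForceTrace(samples=np.linspace(0, 1000, 50), rate=50.0, trigger_index=0)
        elong = ElongationSeries(values=np.linspace(0, 2, 50))
        trial = pair_force_elongation(force, elong, frame_rate=50.0)
        # loading phase: onset at 5% of peak through the peak sample
        assert trial.force[-1] == pytest.approx(1000.0)
        assert np.all(np.diff(trial.force) > 0)
        assert len(trial.force) == len(trial.elongation)

    def test_noise_free_pairs_lie_on_generating_curve(self, clean_trial_spec):
        trial, _, _ = run_trial(clean_trial_spec)
        a, b = clean_trial_spec.curve_a, clean_trial_spec.curve_b
        predicted = a * trial.elongation**2 + b * trial.elongation
        # forces span ~4 kN; the residual budget covers tracking error only
        assert np.abs(predicted - trial.force).max() < 0.01 * trial.peak_force

    def test_frames_past_force_record_rejected(self):
        force = ForceTrace(samples=np.linspace(0, 100, 30), rate=30.0, trigger_index=0)
        elong = ElongationSeries(values=np.zeros(60))
        with pytest.raises(ValueError):
            pair_force_elongation(force, elong, frame_rate=30.0)

    def test_zero_loading_rejected(self):
        force = ForceTrace(samples=np.zeros(100), rate=50.0, trigger_index=0)
        elong = ElongationSeries(values=np.zeros(50))
        with pytest.raises(ValueError):
            pair_force_elongation(force, elong, frame_rate=25.0)


class TestFitTrial:
    def test_exact_quadratic_recovered(self):
        trial = fit_trial(_analytic_trial())
        assert trial.r2 == pytest.approx(1.0, abs=1e-9)
        assert trial.included
        a_fit, b_fit, c_fit = trial.fit
        assert a_fit == pytest.approx(200.0, rel=1e-4)
        assert b_fit == pytest.approx(500.0, rel=1e-4)
        assert abs(c_fit) < 1.0

    def test_white_noise_elongation_excluded(self):
        rng = np.random.default_rng(7)
        trial = ForceElongationTrial(
            force=np.linspace(100, 4000, 80), elongation=rng.normal(0, 1, 80)
        )
        fitted = fit_trial(trial)
        assert fitted.r2 < 0.5 and not fitted.included

    def test_inclusion_boundary_is_inclusive(self):
        """A trial whose R^2 equals the threshold exactly is included."""
        noisy = fit_trial(_analytic_trial(noise_sd=0.3, seed=3))
        assert 0 < noisy.r2 < 1
        at_boundary = fit_trial(_analytic_trial(noise_sd=0.3, seed=3), r2_min=noisy.r2)
        above_boundary = fit_trial(
            _analytic_trial(noise_sd=0.3, seed=3), r2_min=noisy.r2 + 1e-12
        )
        assert at_boundary.included
        assert not above_boundary.included

    def test_r2_responds_monotonically_to_noise(self):
        def r2_at(scale):
            return fit_trial(_analytic_trial(noise_sd=scale, seed=5)).r2

        # the same noise vector scaled up degrades the fit through 0.90
        lo, hi = r2_at(0.05), r2_at(1.5)
        assert lo > 0.90 > hi
        scale_at_090 = brentq(lambda s: r2_at(s) - 0.90, 0.05, 1.5, xtol=1e-12)
        trial = fit_trial(_analytic_trial(noise_sd=scale_at_090, seed=5))
        assert trial.included == (trial.r2 >= 0.90)

    def test_raising_threshold_never_adds_trials(self):
        trials = [_analytic_trial(noise_sd=s, seed=i) for i, s in enumerate((0.0, 0.1, 0.4, 0.9, 1.5))]
        counts = []
        for r2_min in (0.0, 0.5, 0.9, 0.99, 1.0):
            counts.append(sum(fit_trial(t, r2_min=r2_min).included for t in trials))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_trial(_analytic_trial(n=5))

    def test_constant_force_rejected(self):
        trial = ForceElongationTrial(force=np.full(20, 100.0), elongation=np.linspace(0, 1, 20))
        with pytest.raises(ValueError):
            fit_trial(trial)


class TestCommonForce:
    def test_minimum_over_sessions(self):
        assert common_force([3000.0, 3200.0], [3500.0]) == 3000.0

    def test_identical_peaks(self):
        assert common_force([2800.0], [2800.0]) == 2800.0

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            common_force([], [3000.0])


class TestMeanCurve:
    def test_single_trial_equals_its_fit(self):
        trial = fit_trial(_analytic_trial())
        curve = mean_curve([trial], common_force=3000.0)
        assert np.allclose(curve.elongation, trial.elongation_at(curve.force_grid))

    def test_duplicate_trials_change_nothing(self):
        trial = fit_trial(_analytic_trial())
        one = mean_curve([trial], common_force=3000.0)
        two = mean_curve([trial, trial], common_force=3000.0)
        assert np.allclose(one.elongation, two.elongation)
        assert two.n_trials == 2

    def test_mean_of_noisy_trials_converges_to_truth(self):
        trials = [fit_trial(_analytic_trial(noise_sd=0.05, seed=s)) for s in range(24)]
        curve = mean_curve(trials, common_force=3500.0)
        truth = (-500 + np.sqrt(500**2 + 4 * 200 * curve.force_grid)) / (2 * 200)
        assert np.abs(curve.elongation - truth).max() < 0.05

    def test_excluded_trials_ignored(self):
        good = fit_trial(_analytic_trial())
        rng = np.random.default_rng(0)
        bad = fit_trial(ForceElongationTrial(
            force=np.linspace(100, 4000, 80), elongation=rng.normal(0, 1, 80)))
        assert not bad.included
        curve = mean_curve([good, bad], common_force=3000.0)
        assert curve.n_trials == 1


class TestStiffnessSlope:
    def _curve_from_law(self, a, b, cf, n=100):
        grid = np.linspace(0, cf, n)
        e = grid / b if a == 0 else (-b + np.sqrt(b * b + 4 * a * grid)) / (2 * a)
        return MeanCurve(force_grid=grid, elongation=e, common_force=cf, n_trials=1)

    def test_linear_curve_slope(self):
        res = stiffness_slope(self._curve_from_law(0.0, 1000.0, 2000.0))
        assert res.stiffness == pytest.approx(1000.0, rel=1e-9)
        assert res.monotonic

    def test_quadratic_curve_matches_dense_oracle(self):
        res = stiffness_slope(self._curve_from_law(200.0, 500.0, 2000.0))
        oracle = dense_slope_oracle(200.0, 500.0, 2000.0)
        assert res.stiffness == pytest.approx(oracle, rel=1e-3)
        assert res.analysis_range == (pytest.approx(1200.0), pytest.approx(2000.0))

    def test_scaling_elongation_halves_stiffness(self):
        curve = self._curve_from_law(200.0, 500.0, 2000.0)
        doubled = MeanCurve(force_grid=curve.force_grid, elongation=2 * curve.elongation,
                            common_force=curve.common_force, n_trials=1)
        assert stiffness_slope(doubled).stiffness == pytest.approx(
            stiffness_slope(curve).stiffness / 2
        )

    def test_stiffening_curve_upper_slope_exceeds_chord(self):
        curve = self._curve_from_law(200.0, 500.0, 2000.0)
        res = stiffness_slope(curve)
        chord = curve.common_force / curve.elongation[-1]
        assert res.stiffness > chord

    def test_nonmonotonic_range_flagged(self):
        grid = np.linspace(0, 2000.0, 100)
        e = np.linspace(0, 2, 100)
        e[80:] = e[80] - 0.001 * np.arange(20)  # elongation reverses near peak
        curve = MeanCurve(force_grid=grid, elongation=e, common_force=2000.0, n_trials=1)
        assert not stiffness_slope(curve).monotonic
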