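"""Rate smoothing, cosine tuning, circular statistics, PD bootstrap."""

import numpy as np
import pandas as pd
import pytest

from doublering.simulate import RateTensor
from doublering.tuning import (
    TrialSet,
    circular_correlation,
    circular_stats,
    extract_epochs,
    fit_cosine,
    participation_from_amplitudes,
    pd_variability_bootstrap,
    smooth_and_average,
)

TWO_PI = 2 * np.pi
ANGLES8 = TWO_PI * np.arange(8) / 8


def make_rate_trials(rate_fn, n_trials=6, n_units=3, n_conditions=8,
                     seed=0, jitter=0.0):
    """TrialSet from a rate function ``rate_fn(unit, cond, phase)`` where
    ``phase`` in [0, 1] is the piecewise task phase (each of the three
    task intervals maps to a third of the range, matching the time
    normalization applied downstream)."""
    rng = np.random.default_rng(seed)
    rows = []
    traces = {}
    tid = 0
    for _ in range(n_trials):
        for k in range(n_conditions):
            d1 = 0.6 + jitter * rng.uniform(-1, 1)
            d2 = 0.15 + 0.5 * jitter * rng.uniform(-1, 1)
            d3 = 0.3 + 0.5 * jitter * rng.uniform(-1, 1)
            rows.append((tid, k + 1, 0.0, d1, d1 + d2, d1 + d2 + d3))
            t = np.arange(0.0, d1 + d2 + d3 + 1e-9, 0.005)
            phase = np.interp(t, [0, d1, d1 + d2, d1 + d2 + d3],
                              [0, 1 / 3, 2 / 3, 1.0])
            rr = np.stack([rate_fn(i, k, phase) for i in range(n_units)])
            traces[tid] = (t, rr)
            tid += 1
    events = pd.DataFrame(rows, columns=[
        "trial_id", "condition", "t_target", "t_go", "t_move_on",
        "t_move_off"])
    return TrialSet(events, n_units, rates=traces,
                    n_conditions=n_conditions)


class TestSmoothAndAverage:
    def test_single_spike_gives_unit_mass_gaussian_bump(self):
        events = pd.DataFrame(
            [(0, 1, 0.0, 0.5, 0.6, 0.9)],
            columns=["trial_id", "condition", "t_target", "t_go",
                     "t_move_on", "t_move_off"])
        spikes = pd.DataFrame([(0, 0, 0.3)],
                              columns=["trial_id", "unit_id",
                                       "spike_time"])
        trials = TrialSet(events, 1, spikes=spikes, n_conditions=1)
        tensor, _ = smooth_and_average(trials, dt=0.002)
        r = tensor.rates[0, :, 0]
        mass = np.trapezoid(r, tensor.t)
        assert abs(mass - 1.0) < 0.05
        assert abs(tensor.t[np.argmax(r)] - 0.3) < 0.01

    def test_identical_trials_average_to_single_trial(self):
        def fn(i, k, frac):
            return 1.0 + i + np.sin(TWO_PI * frac)
        trials = make_rate_trials(fn, n_trials=3, jitter=0.0)
        tensor, _ = smooth_and_average(trials)
        one = make_rate_trials(fn, n_trials=1, jitter=0.0)
        tensor1, _ = smooth_and_average(one)
        np.testing.assert_allclose(tensor.rates, tensor1.rates,
                                   atol=1e-10)

    def test_time_normalization_recovers_known_profile(self):
        # rate depends only on normalized task time; jittered interval
        # durations must not distort the trial average
        def fn(i, k, phase):
            return 2.0 + np.cos(TWO_PI * phase + i)
        trials = make_rate_trials(fn, n_trials=8, jitter=0.15, seed=3)
        tensor, events = smooth_and_average(trials)
        phase = np.interp(tensor.t,
                          [0.0, events["t_go"], events["t_move_on"],
                           events["t_move_off"]],
                          [0.0, 1 / 3, 2 / 3, 1.0])
        for i in range(3):
            expect = 2.0 + np.cos(TWO_PI * phase + i)
            assert np.abs(tensor.rates[i, :, 0] - expect).max() < 0.02

    def test_trials_with_bad_markers_are_dropped(self):
        def fn(i, k, frac):
            return np.ones_like(frac)
        trials = make_rate_trials(fn, n_trials=2, n_conditions=2)
        trials.events.loc[0, "t_go"] = np.nan
        assert len(trials.valid_trials()) == len(trials.events) - 1


class TestExtractEpochs:
    def _tensor(self):
        t = np.arange(0, 1.5, 0.005)
        rates = np.zeros((3, t.size, 2))
        rates[0] = 1.0
        rates[1] = np.linspace(0, 1, t.size)[None, :, None][0]
        rates[2, :, 0] = np.sin(t)
        return RateTensor(rates, t, np.array([0.0, np.pi]))

    def test_window_arithmetic(self):
        tensor = self._tensor()
        events = {"t_target": 0.0, "t_move_on": 1.0}
        ep = extract_epochs(tensor, events)
        assert np.isclose(ep.prep_window[0], 0.1)
        assert np.isclose(ep.prep_window[1], 0.4)
        assert np.isclose(ep.move_window[0], 0.95)
        assert np.isclose(ep.move_window[1], 1.25)

    def test_configurable_window_lengths(self):
        tensor = self._tensor()
        events = {"t_target": 0.0, "t_move_on": 0.7}
        ep = extract_epochs(tensor, events, prep_length=0.6,
                            move_length=0.6)
        assert np.isclose(ep.prep_window[1] - ep.prep_window[0], 0.6)

    def test_epoch_means_match_hand_computation(self):
        tensor = self._tensor()
        events = {"t_target": 0.0, "t_move_on": 1.0}
        ep = extract_epochs(tensor, events)
        t = tensor.t
        sel = (t >= 0.1 - 1e-9) & (t < 0.4 - 1e-9)
        assert np.isclose(ep.prep_mean[0, 0], 1.0)
        assert np.isclose(ep.prep_mean[2, 0],
                          np.sin(t[sel]).mean(), atol=1e-12)

    def test_window_beyond_span_raises(self):
        tensor = self._tensor()
        with pytest.raises(ValueError, match="exceeds"):
            extract_epochs(tensor, {"t_target": 0.0, "t_move_on": 1.45})


class TestFitCosine:
    def test_exact_cosine_recovered(self):
        y = 2.0 + np.cos(np.pi / 4 - ANGLES8)
        fit = fit_cosine(y, ANGLES8)
        assert np.isclose(fit.a, 2.0)
        assert np.isclose(fit.b, 1.0)
        assert np.isclose(fit.theta_pref, np.pi / 4)
        assert np.isclose(fit.r_squared, 1.0)

    def test_constant_rates_are_untuned(self):
        fit = fit_cosine(np.full(8, 3.0), ANGLES8)
        assert fit.b < 1e-12
        assert np.isnan(fit.theta_pref)

    def test_second_harmonic_residual_closed_form(self):
        # harmonics are orthogonal on the 8-point grid:
        # R^2 = 1 - ||0.5 cos 2phi||^2 / (||cos phi||^2 + ||0.5cos2phi||^2)
        y = 2.0 + np.cos(ANGLES8) + 0.5 * np.cos(2 * ANGLES8)
        fit = fit_cosine(y, ANGLES8)
        assert np.isclose(fit.a, 2.0)
        assert np.isclose(fit.b, 1.0)
        assert np.isclose(fit.theta_pref % TWO_PI, 0.0, atol=1e-12)
        assert np.isclose(fit.r_squared, 1.0 - 1.0 / 5.0)

    def test_scale_equivariance_of_theta_and_eta(self):
        rng = np.random.default_rng(5)
        y = np.abs(rng.standard_normal((12, 8))) + 0.5
        f1 = fit_cosine(y, ANGLES8)
        f2 = fit_cosine(7.0 * y, ANGLES8)
        np.testing.assert_allclose(f2.theta_pref, f1.theta_pref)
        np.testing.assert_allclose(
            participation_from_amplitudes(f2.b),
            participation_from_amplitudes(f1.b))

    def test_eta_normalized_by_population_max(self):
        b = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(participation_from_amplitudes(b),
                                   [0.25, 0.5, 1.0])


class TestCircularStats:
    def test_identical_angles(self):
        s = circular_stats(np.full(5, 1.2))
        assert np.isclose(s.resultant_length, 1.0)
        assert np.isclose(s.circular_variance, 0.0)
        assert np.isclose(s.mean_direction, 1.2)

    def test_symmetric_four_points(self):
        s = circular_stats([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert np.isclose(s.resultant_length, 0.0, atol=1e-15)
        assert np.isclose(s.circular_variance, 1.0)

    def test_two_orthogonal_angles(self):
        s = circular_stats([0.0, np.pi / 2])
        assert np.isclose(s.resultant_length, np.sqrt(2) / 2)
        assert np.isclose(s.circular_variance, 1 - np.sqrt(2) / 2)


class TestCircularCorrelation:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        a = rng.vonmises(1.0, 2.0, 50) % TWO_PI
        assert np.isclose(circular_correlation(a, a), 1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.vonmises(0.5, 2.0, 50) % TWO_PI
        assert np.isclose(circular_correlation(a, (a + 1.3) % TWO_PI),
                          1.0)

    def test_cross_check_against_pingouin(self):
        # independent reference implementation on concentrated samples
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.vonmises(1.0, 3.0, 80)
        b = (0.7 * a + 0.3 * rng.vonmises(0.0, 3.0, 80))
        ours = circular_correlation(a % TWO_PI, b % TWO_PI)
        theirs = pingouin.circ_corrcc(a, b)[0]
        assert abs(ours - theirs) < 1e-10

    def test_correlated_torus_density_population_value(self):
        # draws from the correlated angular density concentrate at chi/2
        rng = np.random.default_rng(3)
        chi = 2 / 3
        n = 40000
        d = np.empty(n)
        count = 0
        while count < n:
            cand = rng.uniform(0, TWO_PI, 2 * n)
            u = rng.uniform(0, 1 + chi, 2 * n)
            acc = cand[u < 1 + chi * np.cos(cand)][:n - count]
            d[count:count + acc.size] = acc
            count += acc.size
        a = rng.uniform(0, TWO_PI, n)
        b = (a - d) % TWO_PI
        rho = circular_correlation(a, b)
        assert abs(rho - chi / 2) < 0.02

    def test_undefined_for_degenerate_denominator(self):
        assert np.isnan(circular_correlation([0.0, 0.0], [1.0, 2.0]))


class TestPDVariabilityBootstrap:
    @staticmethod
    def _trials(pd_fn, n_trials=12, n_units=10, seed=0, noise=0.05):
        """Rate trials whose tuning direction at task-time fraction f is
        pd_fn(unit, f)."""
        rng = np.random.default_rng(seed)

        def fn(i, k, frac):
            phi = ANGLES8[k]
            pd_t = pd_fn(i, frac)
            base = 2.0 + np.cos(pd_t - phi)
            return base + noise * rng.standard_normal(frac.size)
        return make_rate_trials(fn, n_trials=n_trials, n_units=n_units,
                                seed=seed)

    def test_fixed_pd_within_null(self):
        trials = self._trials(lambda i, f: 0.3 * i, seed=1)
        res = pd_variability_bootstrap(trials, B=200, seed=0)
        pct = res.percentile_of_observed("prep")
        assert pct < 99.0
        assert res.observed_median["prep"] < 0.05

    def test_pd_rotation_between_epochs_only(self):
        # PD fixed within epochs, rotates by pi/2 at the go cue
        def pd_fn(i, f):
            return np.where(f < 1 / 3, 0.2 * i, 0.2 * i + np.pi / 2)
        trials = self._trials(pd_fn, seed=2)
        res = pd_variability_bootstrap(trials, B=100, seed=0)
        assert res.observed_median["prep"] < 0.02
        assert res.observed_median["move"] < 0.02
        assert res.observed_median["whole"] > \
            5 * res.observed_median["prep"] + 0.02

    def test_within_epoch_jitter_detected(self):
        # PD wanders by ~20 degrees between bins inside the epoch
        rng = np.random.default_rng(7)

        def pd_fn(i, f):
            return 0.5 * i + 0.35 * np.sin(TWO_PI * 3 * f + i)
        trials = self._trials(pd_fn, seed=3, noise=0.02)
        res = pd_variability_bootstrap(trials, B=200, seed=0)
        null99 = np.percentile(res.null_medians["prep"], 99)
        assert res.observed_median["prep"] > null99
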