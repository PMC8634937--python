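"""Cosinor model, AR(1) likelihood, circular intervals, and daily fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from circwear.cosinor import (BasePrior, CosinorParams, SamplerConfig,
                              ar1_log_likelihood, circular_mean, fit_day,
                              hr_model_predict, phase_credible_interval,
                              sequential_fit)
from circwear.simulate import simulate_day_from_params


class TestModelPrediction:
    def test_minimum_at_phase(self):
        p = CosinorParams(a=70, b=10, c=5, d=0.05)
        assert hr_model_predict(p, 5.0, 0.0) == pytest.approx(60.0)

    def test_maximum_at_antiphase(self):
        p = CosinorParams(a=70, b=10, c=5, d=0.05)
        assert hr_model_predict(p, 17.0, 0.0) == pytest.approx(80.0)

    def test_hand_evaluated_point(self):
        # cos(pi/2) = 0, so prediction = a + d * activity
        p = CosinorParams(a=70, b=10, c=5, d=0.05)
        assert hr_model_predict(p, 11.0, 100.0) == pytest.approx(75.0)

    def test_phase_is_circular(self):
        p1 = CosinorParams(a=70, b=10, c=3, d=0.0)
        t = np.linspace(0, 24, 97)
        th1 = p1.as_array()
        th2 = th1.copy()
        th2[2] += 24.0  # same phase one full turn later
        y = hr_model_predict(p1, t, 0.0)
        ll1 = ar1_log_likelihood(th1, t, y, np.zeros_like(t))
        ll2 = ar1_log_likelihood(th2, t, y, np.zeros_like(t))
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestAr1Likelihood:
    def test_k_zero_equals_independent_gaussian(self):
        rng = np.random.default_rng(0)
        t = np.arange(50) * 5 / 60.0
        act = rng.uniform(0, 100, 50)
        p = CosinorParams(a=70, b=8, c=4, d=0.05, k_ar=0.0, sigma=2.5)
        y = hr_model_predict(p, t, act) + rng.normal(0, 2.5, 50)
        ll = ar1_log_likelihood(p.as_array(), t, y, act)
        resid = y - hr_model_predict(p, t, act)
        expected = stats.norm.logpdf(resid, 0, 2.5).sum()
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_two_term_closed_form(self):
        # zero-prediction model, residuals [1, 1], k = 0.5, sigma = 1
        theta = np.array([0.0, 0.0, 0.0, 0.0, 0.5, 1.0])
        t = np.array([0.0, 5 / 60.0])
        y = np.array([1.0, 1.0])
        ll = ar1_log_likelihood(theta, t, y, np.zeros(2))
        expected = (stats.norm.logpdf(1.0, 0, math.sqrt(1 / 0.75))
                    + stats.norm.logpdf(0.5, 0, 1.0))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_gap_splits_into_independent_runs(self):
        rng = np.random.default_rng(1)
        p = CosinorParams(a=70, b=8, c=4, d=0.0, k_ar=0.6, sigma=2.0)
        t = np.concatenate([np.arange(20), np.arange(40, 60)]) * 5 / 60.0
        y = 70 + rng.normal(0, 2, 40)
        act = np.zeros(40)
        is_start = np.zeros(40, bool)
        is_start[[0, 20]] = True
        ll = ar1_log_likelihood(p.as_array(), t, y, act, is_start)
        ll_a = ar1_log_likelihood(p.as_array(), t[:20], y[:20], act[:20])
        ll_b = ar1_log_likelihood(p.as_array(), t[20:], y[20:], act[20:])
        assert ll == pytest.approx(ll_a + ll_b, rel=1e-12)

    def test_no_usable_bins_raises(self):
        p = CosinorParams(a=70, b=8, c=4, d=0.0)
        with pytest.raises(ValueError):
            ar1_log_likelihood(p.as_array(), np.array([]), np.array([]),
                               np.array([]))


def _brute_circular_interval(samples, level):
    """Independent oracle: quantiles on samples unwrapped about the
    circular mean by explicit shifting."""
    mu = circular_mean(samples)
    unwrapped = [(s - mu + 12.0) % 24.0 - 12.0 + mu for s in samples]
    lo = np.quantile(unwrapped, (1 - level) / 2)
    hi = np.quantile(unwrapped, 1 - (1 - level) / 2)
    return lo % 24.0, hi % 24.0


class TestPhaseInterval:
    def test_point_mass(self):
        lo, hi, half = phase_credible_interval(np.full(100, 6.0))
        assert (lo, hi, half) == (6.0, 6.0, 0.0)

    def test_uniform_arc_across_midnight(self):
        rng = np.random.default_rng(2)
        samples = rng.uniform(23.0, 25.0, 200_000) % 24.0
        lo, hi, half = phase_credible_interval(samples, 0.8)
        assert lo == pytest.approx(23.2, abs=0.02)
        assert hi == pytest.approx(0.8, abs=0.02)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            mu = rng.uniform(0, 24)
            samples = (mu + rng.normal(0, rng.uniform(0.2, 3.0), 5000)) % 24.0
            lo, hi, _ = phase_credible_interval(samples, 0.8)
            olo, ohi = _brute_circular_interval(samples, 0.8)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert hi == pytest.approx(ohi, abs=1e-9)

    def test_default_level_is_80(self):
        import inspect

        sig = inspect.signature(phase_credible_interval)
        assert sig.parameters["level"].default == 0.8


class TestFitDay:
    def test_known_phase_covered_in_most_replicates(self):
        p = CosinorParams(a=70, b=10, c=5.0, d=0.05, k_ar=0.3, sigma=2.0)
        prior = BasePrior()
        hits = 0
        n_rep = 40
        for r in range(n_rep):
            series, _ = simulate_day_from_params(p, seed=500 + r)
            post = fit_day(series, 0, prior, SamplerConfig.fast(seed=r))
            lo, hi, _ = phase_credible_interval(post.samples[:, 2], 0.8)
            span = (hi - lo) % 24.0
            hits += ((5.0 - lo) % 24.0) <= span
        assert hits >= 0.75 * n_rep

    def test_zero_wear_day_returns_prior(self, make_series):
        prior = BasePrior()
        post = fit_day(make_series(), 0, prior, SamplerConfig.fast(seed=0))
        assert not post.fitted and post.n_data == 0
        # prior cloud: phase spread close to uniform
        assert np.std(post.samples[:, 2]) > 4.0

    def test_default_budget_matches_stated_protocol(self):
        cfg = SamplerConfig()
        assert cfg.n_total_evals == 100_000 and cfg.burn_in == 0.5


class TestSequentialFit:
    def test_single_day_equals_fit_day(self, concat_series):
        p = CosinorParams(a=70, b=10, c=5, d=0.05, k_ar=0.3, sigma=2.0)
        series, _ = simulate_day_from_params(p, seed=7)
        cfg = SamplerConfig.fast(seed=5)
        posts, _ = sequential_fit(series, config=cfg)
        direct = fit_day(series, 0, BasePrior(), cfg)
        np.testing.assert_array_equal(posts[0].samples, direct.samples)

    def test_interval_narrows_with_accumulating_days(self, concat_series):
        p = CosinorParams(a=70, b=10, c=5, d=0.05, k_ar=0.3, sigma=2.0)
        days = [simulate_day_from_params(p, seed=200 + d)[0] for d in range(7)]
        _, track = sequential_fit(concat_series(days),
                                  config=SamplerConfig.fast(seed=4))
        late = np.mean(track.half_width_h[4:7])
        assert late <= track.half_width_h[0]

    def test_tracks_phase_step(self, concat_series):
        p = CosinorParams(a=70, b=10, c=5, d=0.05, k_ar=0.3, sigma=2.0)
        days = []
        for d in range(6):
            pd = replace(p, c=5.0 + (2.0 if d >= 3 else 0.0))
            days.append(simulate_day_from_params(pd, seed=100 + d)[0])
        _, track = sequential_fit(concat_series(days),
                                  config=SamplerConfig.fast(seed=3))
        before = track.phase_h[2]
        after = track.phase_h[5]
        # moved at least 1 h toward the +2 h step
        assert (after - before) % 24.0 > 1.0

    def test_uncertainty_grows_with_less_data(self):
        # same generating model, increasing fraction of masked bins;
        # device noise chosen large so interval width carries the signal
        p = CosinorParams(a=70, b=10, c=5, d=0.05, k_ar=0.7, sigma=5.0)
        widths, counts = [], []
        i = 0
        for frac in (0.0, 0.3, 0.5, 0.7, 0.85):
            for _rep in range(3):
                series, _ = simulate_day_from_params(p, seed=900 + i)
                rng = np.random.default_rng(i)
                series.wear[rng.random(288) < frac] = False
                post = fit_day(series, 0, BasePrior(), SamplerConfig.fast(seed=i))
                _, _, half = phase_credible_interval(post.samples[:, 2], 0.8)
                widths.append(half)
                counts.append(post.n_data)
                i += 1
        r, _ = stats.pearsonr(counts, widths)
        assert r < 0
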