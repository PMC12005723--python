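import numpy as np
import pytest

from pulseddm.analyses import (
    ChangeOfMindEvent,
    com_latency_regression,
    detect_com,
    group_by_evidence,
    participation_ratio,
    psth,
    psth_r2,
    psychometric,
    select_tuned_neurons,
    single_trial_rate,
    xcorr_shuffle_corrected,
)


class TestSingleTrialRate:
    def test_zero_spikes(self):
        assert np.all(single_trial_rate(np.zeros(100), 0.01) == 0)

    def test_single_spike_integrates_to_one(self):
        counts = np.zeros(200)
        counts[100] = 1
        rate = single_trial_rate(counts, 0.01, kernel_sd=0.05)
        assert rate.sum() * 0.01 == pytest.approx(1.0, abs=1e-6)
        assert rate[100] == rate.max()

    def test_constant_rate_preserved(self, rng):
        counts = rng.poisson(0.3, 2000)
        rate = single_trial_rate(counts, 0.01)
        interior = rate[50:-50]
        assert interior.mean() == pytest.approx(30.0, rel=0.15)

    def test_multi_axis(self, rng):
        counts = rng.poisson(0.2, (3, 150))
        rate = single_trial_rate(counts, 0.01)
        assert rate.shape == (3, 150)


class TestGrouping:
    def test_equal_sizes(self):
        g = group_by_evidence(np.arange(10)[::-1], groups=2)
        assert sorted(np.bincount(g)) == [5, 5]
        assert np.all(g[np.argsort(np.arange(10)[::-1])[:5]] == 0)

    def test_more_groups(self):
        g = group_by_evidence(np.linspace(-5, 5, 12), groups=4)
        assert np.bincount(g).tolist() == [3, 3, 3, 3]


class TestPsth:
    def test_identical_trials_identical_curves(self):
        rates = [np.ones(50) * 7.0] * 6
        g = np.array([0, 1] * 3)
        avg, cnt = psth(rates, g)
        assert np.allclose(avg[0], avg[1])

    def test_ragged_averaging(self):
        rates = [np.full(30, 2.0), np.full(50, 4.0)]
        avg, cnt = psth(rates, np.array([0, 1]))
        assert np.isnan(avg[0, 40])  # group 0 has no data at t=40
        assert avg[1, 40] == 4.0
        assert cnt[0, 29] == 1 and cnt[0, 30] == 0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            psth([np.ones(10)], np.array([0]), groups=2)


class TestPsthR2:
    def test_perfect_match(self, rng):
        emp = rng.random((2, 40)) + 1
        assert psth_r2(emp, emp.copy()) == pytest.approx(1.0)

    def test_grand_mean_is_zero(self, rng):
        emp = rng.random((2, 40)) + 1
        syn = np.full_like(emp, emp.mean())
        assert psth_r2(emp, syn) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_case(self):
        emp = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        syn = np.array([[1.0, 2.0, 4.0], [1.0, 2.0, 4.0]])
        # SSE = 2, SST = 4 -> R2 = 0.5
        assert psth_r2(emp, syn) == pytest.approx(0.5)

    def test_window_clipping(self):
        emp = np.vstack([np.arange(10.0)] * 2)
        syn = emp + 5.0
        times = np.arange(10) * 0.1
        full = psth_r2(emp, syn, times=times, window=(0.0, 1.0))
        tail = psth_r2(emp, syn, times=times, window=(0.0, 0.2))
        assert full != tail

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            psth_r2(np.ones((2, 5)), np.ones((2, 5)))


class TestXcorr:
    def _indep_poisson(self, rng, n_trials=300, T=60, rate=0.25):
        a = [rng.poisson(rate, T).astype(float) for _ in range(n_trials)]
        b = [rng.poisson(rate, T).astype(float) for _ in range(n_trials)]
        return a, b

    def test_independent_neurons_near_zero(self, rng):
        # unsmoothed PSTHs so the correction term is exact for Poisson data
        # (smoothed PSTHs suppress the edges and leave a positive offset)
        a, b = self._indep_poisson(rng)
        g = np.zeros(len(a), dtype=int)
        g[len(a) // 2:] = 1
        pa, _ = psth([x / 0.01 for x in a], g)
        pb, _ = psth([x / 0.01 for x in b], g)
        taus, corr = xcorr_shuffle_corrected(a, b, pa, pb, g, 0.01, tau_range=0.1)
        # per-tau MC SE here is ~1 Hz against a 25 Hz base rate
        assert np.abs(corr).max() < 5.0
        assert abs(corr.mean()) < 1.0

    def test_self_pair_poisson_peak(self, rng):
        a, _ = self._indep_poisson(rng, n_trials=200)
        g = np.zeros(len(a), dtype=int)
        g[len(a) // 2:] = 1
        pa, _ = psth([single_trial_rate(x, 0.01) for x in a], g)
        taus, corr = xcorr_shuffle_corrected(a, a, pa, pa, g, 0.01, tau_range=0.05)
        i0 = np.argmin(np.abs(taus))
        assert corr[i0] > 5 * np.abs(np.delete(corr, i0)).mean()

    def test_common_latent_positive_central_peak(self, rng):
        # two neurons driven by one slow shared gain
        n_trials, T = 400, 60
        a, b = [], []
        for _ in range(n_trials):
            gain = 1.0 + 0.5 * np.sin(rng.uniform(0, np.pi)) * rng.choice([-1, 1])
            a.append(rng.poisson(0.25 * gain, T).astype(float))
            b.append(rng.poisson(0.25 * gain, T).astype(float))
        g = np.zeros(n_trials, dtype=int)
        g[n_trials // 2:] = 1
        pa, _ = psth([single_trial_rate(x, 0.01) for x in a], g)
        pb, _ = psth([single_trial_rate(x, 0.01) for x in b], g)
        taus, corr = xcorr_shuffle_corrected(a, b, pa, pb, g, 0.01, tau_range=0.1)
        assert corr[np.argmin(np.abs(taus))] > 0

    def test_silent_neuron_raises(self):
        z = [np.zeros(10)]
        with pytest.raises(ValueError):
            xcorr_shuffle_corrected(z, z, np.zeros((2, 10)), np.zeros((2, 10)),
                                    np.array([0]), 0.01)


class TestModelPsth:
    def test_empirical_vs_model_psth_r2(self):
        # well-specified simulation: the evidence-grouped PSTH of simulated
        # spikes approaches the model's expected-rate PSTH (R^2 > 0.9)
        from pulseddm.analyses import model_expected_rates, synthetic_psth
        from pulseddm.inference import ModelSpec, fit_baselines, ModelParams
        from pulseddm.synthetic import SimConfig, make_dataset

        cfg = SimConfig(
            n_trials=1200, n_neurons=1, seed=19, duration_range=(0.4, 0.5),
            slopes=np.array([2.5]), baseline_hz=15.0,
        )
        data = make_dataset(cfg)
        spec = ModelSpec(variant="joint", n_bins=27, refine=5)
        baselines = fit_baselines(data, spec)
        params = ModelParams(
            theta_a=cfg.theta_a, choice=cfg.choice, slopes={"n0": 2.5}
        )
        diffs = np.array([t.train.n_right - t.train.n_left for t in data.trials])
        g = group_by_evidence(diffs, groups=2)
        from pulseddm.stimulus import bin_spikes

        rates = [
            single_trial_rate(
                bin_spikes(t.spikes["n0"], spec.dt, t.train.duration), spec.dt
            )
            for t in data.trials
        ]
        emp, _ = psth(rates, g)
        model_rates = model_expected_rates(
            params, data, spec, baselines, n_reals=20, seed=0
        )
        syn, _ = synthetic_psth(model_rates["n0"], g, spec.dt)
        times = np.arange(emp.shape[1]) * spec.dt
        r2 = psth_r2(emp, syn, times=times, window=(0.0, 0.45))
        assert r2 > 0.9


class TestPsychometric:
    def test_recovers_lapse_logistic(self, rng):
        n = 8000
        x = rng.integers(-15, 16, n).astype(float)
        lapse, slope, bias = 0.1, 0.4, 0.5
        p = lapse / 2 + (1 - lapse) / (1 + np.exp(-(slope * x + bias)))
        y = (rng.random(n) < p).astype(int)
        fit = psychometric(y, x)
        assert fit.slope == pytest.approx(slope, abs=0.05)
        assert fit.bias == pytest.approx(bias, abs=0.15)
        assert fit.lapse == pytest.approx(lapse, abs=0.05)
        # asymptotes at large |click difference|
        assert fit.predict(60.0) == pytest.approx(0.95, abs=0.04)
        assert fit.predict(-60.0) == pytest.approx(0.05, abs=0.04)

    def test_symmetric_data_no_bias(self, rng):
        x = np.concatenate([np.arange(-10, 11)] * 300).astype(float)
        p = 1 / (1 + np.exp(-0.5 * x))
        y = (rng.random(x.size) < p).astype(int)
        fit = psychometric(y, x)
        assert abs(fit.bias) < 0.1

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            psychometric(np.array([0, 1]), np.array([3.0, 3.0]))


class TestDetectCom:
    def test_monotone_no_events(self):
        trace = np.linspace(1, 4, 100)  # never crosses the criterion
        assert detect_com(trace, 0.01, c=0.0) == []
        # slow monotone crossing: |trace| stays < 2 inside the 100 ms window,
        # so the magnitude criterion rejects it
        slow = np.linspace(-4, 4, 100)
        assert detect_com(slow, 0.01, c=0.0) == []
        # steep monotone crossing qualifies
        steep = np.linspace(-4.1, 4.3, 18)
        assert len(detect_com(steep, 0.01, c=0.0)) == 1

    def test_constructed_single_event(self):
        trace = np.concatenate([np.full(8, -3.0), np.full(8, 3.0)])
        events = detect_com(trace, 0.01, c=0.0)
        assert len(events) == 1
        assert events[0].direction == "L->R"
        assert events[0].time == pytest.approx(0.08)

    def test_magnitude_criterion_rejects(self):
        trace = np.concatenate([np.full(8, -1.5), np.full(8, 1.5)])
        assert detect_com(trace, 0.01, c=0.0) == []

    def test_dwell_criterion_rejects(self):
        # bounces back after only 30 ms on the far side
        trace = np.concatenate([np.full(8, -3.0), np.full(3, 3.0), np.full(8, -3.0)])
        events = detect_com(trace, 0.01, c=0.0)
        assert events == []

    def test_resampling_invariance(self):
        trace = np.concatenate([np.full(10, -3.0), np.full(10, 3.0)])
        e1 = detect_com(trace, 0.01, c=0.0)
        fine = np.repeat(trace, 2)
        e2 = detect_com(fine, 0.005, c=0.0)
        assert len(e1) == len(e2) == 1
        assert abs(e1[0].time - e2[0].time) <= 0.005

    def test_short_trace_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            events = detect_com(np.array([1.0, -1.0]), 0.01, c=0.0)
        assert events == []

    def test_nonzero_criterion(self):
        trace = np.concatenate([np.full(8, 0.5), np.full(8, 3.5)])
        events = detect_com(trace, 0.01, c=2.0)
        assert len(events) == 1

    def test_random_monotone_traces_no_false_events(self, rng):
        # monotone traces that never cross the criterion produce no events
        for _ in range(200):
            start = rng.uniform(0.5, 5)
            trace = start + np.cumsum(rng.random(50)) * rng.choice([0.1])
            assert detect_com(trace, 0.01, c=0.0) == []


class TestParticipationRatio:
    def test_independent_channels(self, rng):
        X = rng.standard_normal((20000, 10))
        assert participation_ratio(X) == pytest.approx(10.0, rel=0.05)

    def test_rank_one(self, rng):
        z = rng.standard_normal(5000)
        X = np.outer(z, np.array([1.0, 2.0, -1.0]))
        assert participation_ratio(X) == pytest.approx(1.0, abs=1e-10)

    def test_eigenvalues_two_one(self):
        # analytic: eigenvalues (2, 1) -> 9/5
        lam = np.array([2.0, 1.0])
        assert (lam.sum() ** 2 / (lam**2).sum()) == pytest.approx(1.8)
        # construct data with exactly this covariance
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200000, 2)) * np.sqrt(lam)
        assert participation_ratio(X) == pytest.approx(1.8, rel=0.02)

    def test_invariances(self, rng):
        X = rng.standard_normal((5000, 4)) @ rng.standard_normal((4, 4))
        pr = participation_ratio(X)
        perm = rng.permutation(4)
        assert participation_ratio(X[:, perm]) == pytest.approx(pr, rel=1e-10)
        assert participation_ratio(3.7 * X) == pytest.approx(pr, rel=1e-10)

    def test_three_dim_input(self, rng):
        X = rng.standard_normal((50, 30, 3))
        pr = participation_ratio(X)
        assert 1.0 <= pr <= 3.0

    def test_single_neuron_raises(self, rng):
        with pytest.raises(ValueError):
            participation_ratio(rng.standard_normal((100, 1)))


class TestSelectTuned:
    def test_untuned_rejected(self, rng):
        rates = {
            "a": (rng.normal(10, 2, 250), rng.normal(10, 2, 250)),
        }
        # identical distributions: kept only with probability alpha
        rejected = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            rates = {"a": (r.normal(10, 2, 250), r.normal(10, 2, 250))}
            rejected += select_tuned_neurons(rates) == []
        assert rejected >= 18

    def test_tuned_kept(self, rng):
        rates = {
            "tuned": (rng.normal(10, 3, 200), rng.normal(20, 3, 200)),
            "flat": (rng.normal(15, 3, 200), rng.normal(15, 3, 200)),
        }
        kept = select_tuned_neurons(rates)
        assert "tuned" in kept

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            select_tuned_neurons({"a": (np.array([1.0]), np.array([2.0, 3.0]))})


class TestComLatencyRegression:
    def test_perfect_linear(self):
        x = np.array([-0.5, -0.3, -0.1, 0.0])
        y = 2.0 * x + 0.1
        slope, p = com_latency_regression(x, y)
        assert slope == pytest.approx(2.0)
        assert p < 0.01

    def test_shuffled_null(self, rng):
        x = rng.uniform(-1, 0, 200)
        y = rng.uniform(0, 0.5, 200)
        slope, p = com_latency_regression(x, y)
        assert abs(slope) < 0.2
        assert p > 0.001  # overwhelmingly likely for independent data

    def test_duplicate_x(self):
        x = np.array([0.1, 0.1, 0.2, 0.2, 0.3])
        y = np.array([1.0, 2.0, 1.5, 2.5, 2.0])
        slope, p = com_latency_regression(x, y)
        assert np.isfinite(slope) and np.isfinite(p)

    def test_needs_three_events(self):
        with pytest.raises(ValueError):
            com_latency_regression(np.array([0.1, 0.2]), np.array([1.0, 2.0]))

    def test_constant_regressor(self):
        with pytest.raises(ValueError):
            com_latency_regression(np.full(5, 0.1), np.arange(5.0))
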