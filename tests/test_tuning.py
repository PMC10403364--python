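"""Tuning models: sigmoid fits, lags, derivative model, test dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pherospace.synthetic import (ForwardModelParams, PRESENTATION_SPEEDS,
                                  PRINTED_DISTANCES, StimulusScript,
                                  logistic_response, simulate_orn_trace)
from pherospace.traces import DffTrace, TrialSet
from pherospace.tuning import (TuningCurve, build_distance_tuning,
                               crosscorr_lag, fit_sigmoid,
                               positive_derivative_model,
                               speed_model_regression, stat_dispatch)


def synthetic_curve(params, noise_sd=0.0, n_flies=8, n_trials=3, seed=0):
    d = np.repeat(PRINTED_DISTANCES, n_flies * n_trials)
    fly = np.tile(np.repeat(np.arange(n_flies), n_trials),
                  len(PRINTED_DISTANCES))
    y = logistic_response(d, params)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(d))
    return TuningCurve(distances=d, responses=y, fly_ids=fly)


class TestFitSigmoid:
    @pytest.mark.parametrize("top,base,ed50,slope", [
        (1.0, 0.0, 2.4, 0.5),
        (1.0, 0.05, 2.2, 0.4),
        (0.8, 0.1, 1.5, 0.3),
    ])
    def test_exact_recovery_on_noiseless_data(self, top, base, ed50, slope):
        p = ForwardModelParams(top=top, base=base, ed50=ed50, slope=slope,
                               noise_sd=0.0)
        fit = fit_sigmoid(synthetic_curve(p))
        assert fit.ed50 == pytest.approx(ed50, abs=1e-6)
        assert fit.slope == pytest.approx(slope, abs=1e-6)
        assert fit.rse == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_matches_grid_search_oracle(self):
        p = ForwardModelParams(top=1.0, base=0.0, ed50=2.4, slope=0.5)
        curve = synthetic_curve(p, noise_sd=0.05, seed=11)
        fit = fit_sigmoid(curve)
        # brute-force least squares over (ed50, slope), top/base analytic-free
        d, y, _ = curve.mean_by_distance()
        best = (np.inf, None)
        for e in np.arange(1.5, 3.5, 0.01):
            for s in np.arange(0.2, 1.2, 0.01):
                f = 1.0 / (1.0 + np.exp((d - e) / s))
                A = np.column_stack([f, np.ones_like(f)])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = np.sum((y - A @ coef) ** 2)
                if rss < best[0]:
                    best = (rss, e)
        assert fit.ed50 == pytest.approx(best[1], abs=0.02)

    def test_flat_data_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            fit_sigmoid(TuningCurve(distances=np.array([1.0, 2, 3, 4]),
                                    responses=np.ones(4),
                                    fly_ids=np.zeros(4)))


class TestBuildDistanceTuning:
    def _trials(self, n_flies=8, n_trials=3, seed=0):
        p = ForwardModelParams(noise_sd=0.0)
        traces = {}
        for f in range(n_flies):
            for t in range(n_trials):
                for d in PRINTED_DISTANCES:
                    y = np.r_[np.zeros(5), np.full(10, logistic_response(d, p))]
                    traces[(f, t, d)] = DffTrace(samples=y, fs=10.0,
                                                 stim_onset=0.45,
                                                 stim_offset=1.4)
        return TrialSet(traces=traces)

    def test_bookkeeping(self):
        curve = build_distance_tuning(self._trials(), normalize=False)
        assert len(curve.unique_distances) == 10
        assert len(curve.responses) == 10 * 8 * 3

    def test_sem_of_identical_fly_means_is_zero(self):
        _, _, sems = build_distance_tuning(
            self._trials(), normalize=False).mean_by_distance()
        assert np.allclose(sems, 0.0)

    def test_sem_matches_hand_computation(self, rng):
        curve = build_distance_tuning(self._trials(), normalize=False)
        # perturb one distance's per-fly means by hand and recompute
        d0 = curve.unique_distances[0]
        sel = curve.distances == d0
        resp = curve.responses.copy()
        resp[sel] += rng.normal(0, 0.2, sel.sum())
        curve2 = TuningCurve(distances=curve.distances, responses=resp,
                             fly_ids=curve.fly_ids)
        dists, _, sems = curve2.mean_by_distance()
        flies = np.unique(curve2.fly_ids[sel])
        fm = [resp[sel & (curve2.fly_ids == f)].mean() for f in flies]
        expect = np.std(fm, ddof=1) / np.sqrt(len(fm))
        assert sems[list(dists).index(d0)] == pytest.approx(expect)


class TestCrosscorrLag:
    def test_identical_signals_lag_zero(self, rng):
        x = np.cumsum(rng.normal(0, 1, 300))
        res = crosscorr_lag(-x, x, fs=7.2)
        assert res.lag_s == 0.0
        assert res.peak_correlation == pytest.approx(1.0)

    def test_constructed_shift_gives_printed_quantization(self, rng):
        x = np.cumsum(rng.normal(0, 1, 500))
        y = np.r_[np.zeros(4), -x[:-4]]
        res = crosscorr_lag(y, x, fs=7.2)
        assert res.lag_s == pytest.approx(4 / 7.2)
        assert res.lag_s == pytest.approx(0.556, abs=1e-3)

    def test_inversion_sign_convention(self):
        # a monotone approach: distance falls while the response grows
        x = np.linspace(5.0, 0.5, 300)
        inverted = crosscorr_lag(-x, x, fs=7.2, invert_distance=True)
        raw = crosscorr_lag(-x, x, fs=7.2, invert_distance=False)
        assert inverted.peak_correlation > 0
        assert raw.peak_correlation < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            crosscorr_lag(np.ones(50), np.ones(50), fs=10.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        from scipy.stats import pearsonr
        r = np.random.default_rng(seed)
        x = np.cumsum(r.normal(0, 1, 80))
        y = np.cumsum(r.normal(0, 1, 80))
        fs, max_lag = 10.0, 1.0
        res = crosscorr_lag(y, x, fs=fs, max_lag=max_lag)
        best = (-np.inf, 0)
        for k in range(-10, 11):
            a = y[k:] if k >= 0 else y[:k]
            b = x[:len(x) - k] if k >= 0 else x[-k:]
            rho = pearsonr(a, -b).statistic
            if rho > best[0]:
                best = (rho, k)
        assert res.lag_s == pytest.approx(best[1] / fs)
        assert res.peak_correlation == pytest.approx(best[0])


class TestDerivativeModel:
    def test_linear_ramp_gives_constant_slope(self):
        fs = 10.0
        t = np.arange(0, 5, 1 / fs)
        tr = DffTrace(samples=0.2 * t, fs=fs, stim_onset=0.1, stim_offset=4.9)
        out = positive_derivative_model(tr)
        assert np.allclose(out.samples, 0.2)

    def test_decreasing_trace_rectified_to_zero(self):
        tr = DffTrace(samples=np.linspace(1, 0, 30), fs=10.0,
                      stim_onset=0.1, stim_offset=2.8)
        assert np.all(positive_derivative_model(tr).samples == 0.0)

    def test_quadratic_matches_symbolic_derivative(self):
        fs = 100.0
        t = np.arange(0, 2, 1 / fs)
        tr = DffTrace(samples=t**2, fs=fs, stim_onset=0.01, stim_offset=1.9)
        out = positive_derivative_model(tr)
        assert np.allclose(out.samples, 2 * t[1:], atol=2 / fs)

    def test_exact_linear_relation_recovers_slope(self):
        p = ForwardModelParams(noise_sd=0.0)
        traces = {s: simulate_orn_trace(p, StimulusScript.approach(s),
                                        "center", fs=20.0)
                  for s in PRESENTATION_SPEEDS}
        dpeaks = {s: float(np.max(positive_derivative_model(tr).samples))
                  for s, tr in traces.items()}
        observed = {s: 2.0 * dpeaks[s] for s in dpeaks}
        fit = speed_model_regression(traces, observed)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_derivative_peaks_increase_with_speed(self):
        p = ForwardModelParams(noise_sd=0.0)
        peaks = []
        for s in PRESENTATION_SPEEDS:
            tr = simulate_orn_trace(p, StimulusScript.approach(s), "center",
                                    fs=20.0)
            peaks.append(np.max(positive_derivative_model(tr).samples))
        assert peaks[0] < peaks[1] < peaks[2]

    def test_uncorrelated_noise_gives_low_r2(self, rng):
        p = ForwardModelParams(noise_sd=0.0)
        speeds = np.linspace(1, 10, 12)
        traces = {s: simulate_orn_trace(p, StimulusScript.approach(float(s)),
                                        "center", fs=20.0) for s in speeds}
        r2s = []
        for rep in range(20):
            observed = {s: rng.normal() for s in speeds}
            r2s.append(speed_model_regression(traces, observed).r_squared)
        assert np.median(r2s) < 0.3


class TestStatDispatch:
    def test_normal_samples_take_parametric_branch(self):
        r = np.random.default_rng(6)
        rep = stat_dispatch([r.normal(0, 1, 20), r.normal(0, 1, 20)],
                            design="unpaired")
        assert rep["test"] == "unpaired t-test"

    def test_skewed_sample_takes_nonparametric_branch(self):
        r = np.random.default_rng(0)
        a = np.exp(r.normal(0, 1.5, 30))  # heavily skewed
        b = r.normal(0, 1, 30)
        rep = stat_dispatch([a, b], design="unpaired")
        assert rep["test"] == "wilcoxon rank-sum"

    def test_identical_groups_give_large_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rep = stat_dispatch([a, a.copy()], design="unpaired")
        assert rep["p_value"] > 0.9

    def test_repeated_design_runs_friedman_with_bh_posthoc(self):
        r = np.random.default_rng(1)
        base = r.normal(0, 1, 12)
        groups = [base, base + 1.0, base + 2.0]
        rep = stat_dispatch(groups, design="repeated")
        assert rep["test"] == "friedman"
        assert len(rep["posthoc"]) == 3
        praw = [h["p_value"] for h in rep["posthoc"]]
        padj = [h["p_adjusted"] for h in rep["posthoc"]]
        assert all(q >= p - 1e-15 for p, q in zip(praw, padj))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_bh_adjustment_monotone_and_never_decreases(self, pvals):
        from pherospace.tuning import _bh_adjust
        padj = _bh_adjust(pvals)
        assert np.all(padj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(np.asarray(padj)[order]) >= -1e-12)
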