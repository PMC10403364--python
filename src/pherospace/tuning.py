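"""Stimulus–response tuning models.

Sigmoidal distance tuning (four-parameter logistic with ED50 and residual
standard error), stimulus–response cross-correlation lags, the positive
first-derivative (approach-speed) model, and the normality-gated
statistical test dispatch used throughout the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as _stats
from statsmodels.stats.multitest import multipletests

from .traces import DffTrace, TrialSet, peak_response

__all__ = [
    "TuningCurve",
    "SigmoidFit",
    "LagResult",
    "DerivativeModelFit",
    "fit_sigmoid",
    "build_distance_tuning",
    "crosscorr_lag",
    "positive_derivative_model",
    "speed_model_regression",
    "stat_dispatch",
]


@dataclass(frozen=True)
class TuningCurve:
    """Per-observation normalized peak responses at a set of distances.

    ``distances``/``responses``/``fly_ids`` are parallel per-observation
    arrays (one row per fly × trial).
    """

    distances: np.ndarray  # mm, per observation
    responses: np.ndarray  # normalized peaks, per observation
    fly_ids: np.ndarray
    cell_type: str = ""

    def __post_init__(self):
        for name in ("distances", "responses", "fly_ids"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        if len(np.unique(self.distances)) < 4:
            raise ValueError("need at least 4 distinct distances to fit")

    @property
    def unique_distances(self) -> np.ndarray:
        return np.unique(self.distances)

    def mean_by_distance(self):
        """Across-fly mean of per-fly trial means at each distance, and
        the SEM over flies (biological replicates)."""
        dists = self.unique_distances
        means = np.empty(len(dists))
        sems = np.empty(len(dists))
        for k, d in enumerate(dists):
            sel = self.distances == d
            flies = np.unique(self.fly_ids[sel])
            fm = np.array([self.responses[sel & (self.fly_ids == f)].mean()
                           for f in flies])
            means[k] = fm.mean()
            sems[k] = fm.std(ddof=1) / np.sqrt(len(fm)) if len(fm) > 1 else 0.0
        return dists, means, sems


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic distance-tuning fit.

    R(d) = base + (top − base) / (1 + exp((d − ed50) / slope)); ``rse``
    is the residual standard error sqrt(RSS / (n − 4)).
    """

    top: float
    base: float
    ed50: float  # mm
    slope: float  # mm
    rse: float
    n_obs: int
    converged: bool = True

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        out = self.base + (self.top - self.base) / (
            1.0 + np.exp((d - self.ed50) / self.slope))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LagResult:
    """Cross-correlation lag: positive = the stimulus leads and the
    neural signal follows."""

    lag_s: float
    peak_correlation: float


@dataclass(frozen=True)
class DerivativeModelFit:
    """Regression of observed third-order peaks on the positive
    derivative peaks of the PN input, across approach speeds."""

    speeds: np.ndarray
    derivative_peaks: np.ndarray
    observed_peaks: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def _logistic(d, top, base, ed50, slope):
    return base + (top - base) / (1.0 + np.exp((d - ed50) / slope))


def _self_start(d: np.ndarray, y: np.ndarray):
    """Initial logistic parameters by log-linearization."""
    top0 = float(y.max())
    base0 = float(y.min())
    span = top0 - base0
    # pad so the logit is finite at the extremes
    ys = np.clip((y - base0) / max(span, 1e-12), 1e-3, 1 - 1e-3)
    z = np.log((1.0 - ys) / ys)  # z ≈ (d − ed50)/slope
    A = np.column_stack([d, np.ones_like(d)])
    (b1, b0), *_ = np.linalg.lstsq(A, z, rcond=None)
    slope0 = 1.0 / b1 if b1 > 1e-9 else np.ptp(d) / 4.0
    ed500 = -b0 * slope0 if b1 > 1e-9 else float(np.median(d))
    lo, hi = float(d.min()), float(d.max())
    ed500 = min(max(ed500, lo), hi)
    return top0, base0, ed500, max(slope0, 1e-3)


def fit_sigmoid(curve: TuningCurve, on_means: bool = True) -> SigmoidFit:
    """Nonlinear least-squares logistic fit of response against distance.

    By default the fit is to the per-distance mean responses (one point
    per presentation distance), self-started by log-linearizing a
    logistic through the data. ``rse = sqrt(RSS / (n − 4))``.
    """
    if on_means:
        d, y, _ = curve.mean_by_distance()
    else:
        d, y = curve.distances.astype(float), curve.responses.astype(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.ptp(y) < 1e-12:
        raise ValueError("degenerate flat data: no response variation to fit")
    p0 = _self_start(d, y)
    try:
        popt, _ = optimize.curve_fit(
            _logistic, d, y, p0=p0, maxfev=20_000,
            bounds=([-np.inf, -np.inf, 1e-6, 1e-6], [np.inf, np.inf, np.inf, np.inf]))
        converged = True
    except RuntimeError:
        popt, converged = np.asarray(p0), False
    resid = y - _logistic(d, *popt)
    n = len(y)
    rse = float(np.sqrt(np.sum(resid**2) / (n - 4))) if n > 4 else float("nan")
    return SigmoidFit(top=float(popt[0]), base=float(popt[1]),
                      ed50=float(popt[2]), slope=float(popt[3]),
                      rse=rse, n_obs=n, converged=converged)


def build_distance_tuning(trials: TrialSet, cell_type: str = "",
                          normalize: bool = True) -> TuningCurve:
    """Per-fly per-trial normalized peaks grouped by presentation distance.

    ``trials`` keys are (fly_id, trial, distance); each trace's peak is
    taken over its stimulus epoch. When ``normalize`` is set, peaks are
    divided by the per-ROI maximum (largest value over the experiment).
    """
    from .traces import normalize_by_roi_max
    if normalize:
        trials = normalize_by_roi_max(trials)
    dist, resp, fly = [], [], []
    for (fly_id, trial, condition), trace in trials.traces.items():
        if condition is None:
            raise ValueError("trial missing its distance annotation")
        dist.append(float(condition))
        resp.append(peak_response(trace))
        fly.append(fly_id)
    return TuningCurve(distances=np.array(dist), responses=np.array(resp),
                       fly_ids=np.array(fly), cell_type=cell_type)


def crosscorr_lag(neural: "DffTrace | np.ndarray", distance, fs: float | None = None,
                  max_lag: float = 5.0, invert_distance: bool = True) -> LagResult:
    """Lag of maximal cross-correlation between a neural signal and the
    male distance.

    The distance is negated before correlating (closer male → larger
    response), so a well-tracking signal gives a *positive* peak
    correlation. Positive lag means the stimulus leads and the neural
    signal follows; the lag is reported on the sample grid (1/fs).
    """
    if isinstance(neural, DffTrace):
        y = neural.samples
        fs = neural.fs
    else:
        y = np.asarray(neural, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    x = np.asarray(distance, dtype=float)
    if invert_distance:
        x = -x
    if len(x) != len(y):
        raise ValueError("signals must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    max_shift = int(round(max_lag * fs))
    best = (-np.inf, 0)
    for shift in range(-max_shift, max_shift + 1):
        # positive shift: y (neural) lags x (stimulus) by `shift` samples
        if shift >= 0:
            a, b = y[shift:], x[:len(x) - shift]
        else:
            a, b = y[:shift], x[-shift:]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best[0]:
            best = (r, shift)
    return LagResult(lag_s=best[1] / fs, peak_correlation=best[0])


def positive_derivative_model(lpn: DffTrace) -> DffTrace:
    """Rectified first derivative of a (pre-smoothed) PN trace.

    First difference times the sampling rate, with negative values set to
    zero — the looming-detector abstraction of a cell that responds to
    the approach phase only.
    """
    if len(lpn.samples) < 2:
        raise ValueError("trace shorter than 2 samples")
    deriv = np.clip(np.diff(lpn.samples) * lpn.fs, 0.0, None)
    return lpn.with_samples(deriv)


def speed_model_regression(lpn_traces: dict, observed_peaks: dict) -> DerivativeModelFit:
    """OLS of observed peaks on the PN derivative peaks across speeds.

    ``lpn_traces`` maps speed → DffTrace (PN response at that approach
    speed); ``observed_peaks`` maps speed → measured peak of the
    downstream cell. Returns slope, intercept and R².
    """
    speeds = sorted(lpn_traces)
    if len(speeds) < 2:
        raise ValueError("need at least two speeds")
    dpeaks = np.array([float(np.max(positive_derivative_model(lpn_traces[s]).samples))
                       for s in speeds])
    opeaks = np.array([float(observed_peaks[s]) for s in speeds])
    if np.var(dpeaks) == 0:
        raise ValueError("zero variance in the derivative peaks")
    A = np.column_stack([dpeaks, np.ones_like(dpeaks)])
    (slope, intercept), *_ = np.linalg.lstsq(A, opeaks, rcond=None)
    resid = opeaks - (slope * dpeaks + intercept)
    ss_tot = np.sum((opeaks - opeaks.mean())**2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / float(ss_tot)
    return DerivativeModelFit(speeds=np.array(speeds, dtype=float),
                              derivative_peaks=dpeaks, observed_peaks=opeaks,
                              slope=float(slope), intercept=float(intercept),
                              r_squared=float(r2))


def _bh_adjust(pvals):
    return multipletests(pvals, method="fdr_bh")[1]


def stat_dispatch(groups, design: str = "unpaired", alpha: float = 0.05) -> dict:
    """Normality-gated statistical test dispatch.

    * ``unpaired`` (2 groups): Shapiro–Wilk on both groups and an F-test
      of equal variances; if all pass (p > α) an unpaired t-test is used,
      otherwise a Wilcoxon rank-sum test.
    * ``paired`` (2 groups): the same gates on the paired differences;
      paired t-test or Wilcoxon signed-rank.
    * ``multigroup``: Kruskal–Wallis, followed by pairwise rank-sum tests
      with Benjamini–Hochberg correction.
    * ``repeated``: Friedman test, followed by pairwise signed-rank tests
      with Benjamini–Hochberg correction.

    Returns a report dict with the chosen test, statistic, p-value and,
    where applicable, BH-adjusted pairwise p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 3 for g in groups):
        raise ValueError("need at least three observations per group")
    report: dict = {"design": design, "alpha": alpha}

    if design == "unpaired":
        a, b = groups[:2]
        sw_a, sw_b = _stats.shapiro(a).pvalue, _stats.shapiro(b).pvalue
        f = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        dfa, dfb = len(a) - 1, len(b) - 1
        p_f = 2.0 * min(_stats.f.cdf(f, dfa, dfb), _stats.f.sf(f, dfa, dfb))
        report.update(shapiro_p=(float(sw_a), float(sw_b)), f_test_p=float(p_f))
        if sw_a > alpha and sw_b > alpha and p_f > alpha:
            res = _stats.ttest_ind(a, b)
            report.update(test="unpaired t-test")
        else:
            res = _stats.mannwhitneyu(a, b, alternative="two-sided")
            report.update(test="wilcoxon rank-sum")
        report.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    elif design == "paired":
        a, b = groups[:2]
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        diff = a - b
        sw = _stats.shapiro(diff).pvalue
        report.update(shapiro_p=float(sw))
        if sw > alpha:
            res = _stats.ttest_rel(a, b)
            report.update(test="paired t-test")
        else:
            res = _stats.wilcoxon(a, b)
            report.update(test="wilcoxon signed-rank")
        report.update(statistic=float(res.statistic), p_value=float(res.pvalue))
    elif design in ("multigroup", "repeated"):
        if design == "multigroup":
            omni = _stats.kruskal(*groups)
            report.update(test="kruskal-wallis")
            pair_test = lambda x, y: _stats.mannwhitneyu(  # noqa: E731
                x, y, alternative="two-sided")
        else:
            omni = _stats.friedmanchisquare(*groups)
            report.update(test="friedman")
            pair_test = lambda x, y: _stats.wilcoxon(x, y)  # noqa: E731
        report.update(statistic=float(omni.statistic), p_value=float(omni.pvalue))
        pairs, praw = [], []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                res = pair_test(groups[i], groups[j])
                pairs.append((i, j, float(res.statistic), float(res.pvalue)))
                praw.append(res.pvalue)
        padj = _bh_adjust(praw)
        report["posthoc"] = [
            {"pair": (i, j), "statistic": s, "p_value": p, "p_adjusted": float(q)}
            for (i, j, s, p), q in zip(pairs, padj)]
    else:
        raise ValueError(f"unknown design {design!r}")
    return report
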