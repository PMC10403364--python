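"""Fluorescence-trace preprocessing.

Turns raw calcium-indicator fluorescence into the normalized per-trial
response statistics (ΔF/F₀, peaks, means, rise times, adaptation indices)
that every downstream tuning and decoding analysis consumes.

Conventions
-----------
* ΔF/F₀ uses a baseline window from 1 s after the start of the imaging
  sweep up to (but excluding) stimulus onset.
* Traces are gently smoothed with a zero-phase low-pass Butterworth filter
  (order 2, 1 Hz cutoff by default) so that smoothing introduces no lag
  bias into cross-correlation analyses.
* Normalization is per ROI, by the largest ΔF/F₀ value that ROI reached
  over the whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "RawTrace",
    "DffTrace",
    "TrialSet",
    "PoseTrace",
    "compute_dff",
    "lowpass_smooth",
    "normalize_by_roi_max",
    "peak_response",
    "mean_response",
    "half_rise_time",
    "adaptation_index",
    "clean_pose_trace",
]

DEFAULT_FS = 7.2  # Hz, imaging sampling rate


@dataclass(frozen=True)
class RawTrace:
    """A raw fluorescence sweep from one ROI.

    Parameters
    ----------
    samples : array of fluorescence values (arbitrary units)
    fs : sampling rate in Hz
    sweep_start : time of the first sample, s
    stim_onset, stim_offset : stimulus epoch, s (absolute, same clock as
        ``sweep_start``)
    roi_id : ROI label
    side : ``"left"``, ``"right"`` or ``"none"``
    """

    samples: np.ndarray
    fs: float
    sweep_start: float
    stim_onset: float
    stim_offset: float
    roi_id: str = "roi0"
    side: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.sweep_start < self.stim_onset < self.stim_offset):
            raise ValueError("require sweep_start < stim_onset < stim_offset")
        end = self.sweep_start + len(self.samples) / self.fs
        if self.stim_offset > end + 1e-9:
            raise ValueError("stimulus epoch extends past the end of the trace")

    @property
    def times(self) -> np.ndarray:
        return self.sweep_start + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class DffTrace:
    """A ΔF/F₀ time series with its stimulus epoch.

    ``samples`` are dimensionless fractional changes relative to the
    baseline fluorescence ``f0``; ``stim_onset``/``stim_offset`` are on the
    same absolute clock as ``sweep_start``.
    """

    samples: np.ndarray
    fs: float
    stim_onset: float
    stim_offset: float
    sweep_start: float = 0.0
    f0: float = 1.0
    roi_id: str = "roi0"
    side: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.sweep_start + np.arange(len(self.samples)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "DffTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class TrialSet:
    """ΔF/F₀ traces grouped by (fly, trial, condition).

    ``traces`` maps ``(fly_id, trial, condition)`` -> DffTrace. All member
    traces must share a sampling rate. ``norm_constants`` records the
    per-ROI maximum used by :func:`normalize_by_roi_max`.
    """

    traces: dict
    norm_constants: dict = field(default_factory=dict)

    def __post_init__(self):
        rates = {t.fs for t in self.traces.values()}
        if len(rates) > 1:
            raise ValueError("all traces in a TrialSet must share fs")

    def by_roi(self) -> dict:
        out: dict = {}
        for key, tr in self.traces.items():
            out.setdefault(tr.roi_id, []).append((key, tr))
        return out


@dataclass(frozen=True)
class PoseTrace:
    """Per-frame tracked keypoint (x, y, confidence) at sampling rate fs."""

    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    fs: float

    def __post_init__(self):
        for name in ("x", "y", "confidence"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.x) == len(self.y) == len(self.confidence)):
            raise ValueError("x, y, confidence must have equal length")
        c = self.confidence
        if np.any((c < 0) | (c > 1)):
            raise ValueError("confidence must lie in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def _baseline_window(raw: RawTrace) -> np.ndarray:
    """Indices of frames in [sweep_start + 1 s, stim_onset) — half-open."""
    t = raw.times
    mask = (t >= raw.sweep_start + 1.0) & (t < raw.stim_onset)
    return np.nonzero(mask)[0]


def compute_dff(raw: RawTrace) -> DffTrace:
    """ΔF/F₀ with F₀ = mean fluorescence from 1 s after sweep start to
    stimulus onset.

    Raises
    ------
    ValueError
        If the baseline window is empty or the baseline mean is not
        positive.
    """
    idx = _baseline_window(raw)
    if idx.size == 0:
        raise ValueError("baseline window [sweep_start + 1 s, stim_onset) is empty")
    f0 = float(np.mean(raw.samples[idx]))
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence F0 = {f0:g} must be positive")
    return DffTrace(
        samples=(raw.samples - f0) / f0,
        fs=raw.fs,
        stim_onset=raw.stim_onset,
        stim_offset=raw.stim_offset,
        sweep_start=raw.sweep_start,
        f0=f0,
        roi_id=raw.roi_id,
        side=raw.side,
    )


def lowpass_smooth(trace: DffTrace, cutoff: float = 1.0, order: int = 2) -> DffTrace:
    """Zero-phase low-pass Butterworth smoothing (forward–backward).

    DC is preserved exactly; because the filter is applied in both
    directions there is no phase lag.
    """
    nyq = trace.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq:g}) Hz")
    sos = _signal.butter(order, cutoff, btype="low", fs=trace.fs, output="sos")
    smoothed = _signal.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(smoothed)


def normalize_by_roi_max(trials: TrialSet) -> TrialSet:
    """Normalize each ROI's traces by its largest value over the experiment.

    After normalization the per-ROI maximum is exactly 1. The operation is
    idempotent and records the constants used.
    """
    by_roi = trials.by_roi()
    consts: dict = {}
    new_traces: dict = {}
    for roi, members in by_roi.items():
        m = max(float(np.max(tr.samples)) for _, tr in members)
        if m <= 0:
            raise ValueError(f"ROI {roi!r} has no positive value to normalize by")
        consts[roi] = m
        for key, tr in members:
            new_traces[key] = tr.with_samples(tr.samples / m)
    return TrialSet(traces=new_traces, norm_constants=consts)


def _window_indices(trace: DffTrace, window: tuple[float, float]) -> np.ndarray:
    t = trace.times
    lo, hi = window
    idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"window {window} contains no samples")
    return idx


def peak_response(trace: DffTrace, window: tuple[float, float] | None = None) -> float:
    """Maximum of the trace within ``window`` (default: the stimulus epoch)."""
    if window is None:
        window = (trace.stim_onset, trace.stim_offset)
    return float(np.max(trace.samples[_window_indices(trace, window)]))


def mean_response(trace: DffTrace, window: tuple[float, float] | None = None) -> float:
    """Mean of the trace within ``window`` (default: the stimulus epoch)."""
    if window is None:
        window = (trace.stim_onset, trace.stim_offset)
    return float(np.mean(trace.samples[_window_indices(trace, window)]))


def half_rise_time(trace: DffTrace) -> float:
    """Time from stimulus onset to the first crossing of half the peak.

    Linear interpolation between the samples that bracket the crossing.
    Raises if the trace never reaches half-peak after onset.
    """
    t = trace.times
    on_idx = int(np.searchsorted(t, trace.stim_onset))
    y = trace.samples[on_idx:]
    if y.size < 2:
        raise ValueError("trace too short after stimulus onset")
    baseline = y[0]
    peak = float(np.max(y))
    if peak <= baseline:
        raise ValueError("no rise above the onset level")
    half = 0.5 * peak
    above = np.nonzero(y >= half)[0]
    if above.size == 0:
        raise ValueError("trace never crosses half of its peak")
    i = int(above[0])
    t_rel = (t[on_idx:] - trace.stim_onset)
    if i == 0:
        return float(t_rel[0])
    # interpolate between samples i-1 and i
    y0, y1 = y[i - 1], y[i]
    frac = (half - y0) / (y1 - y0)
    return float(t_rel[i - 1] + frac * (t_rel[i] - t_rel[i - 1]))


def adaptation_index(trace: DffTrace) -> float:
    """End-of-stimulus response divided by the peak response.

    1 for a non-adapting plateau; lower values indicate stronger
    adaptation. The end value is the sample nearest the stimulus offset.
    """
    peak = peak_response(trace)
    if peak <= 0:
        raise ValueError("peak response must be positive")
    t = trace.times
    end_idx = int(np.argmin(np.abs(t - trace.stim_offset)))
    return float(trace.samples[end_idx] / peak)


def clean_pose_trace(
    pose: PoseTrace,
    min_conf: float = 0.7,
    target_fs: float = DEFAULT_FS,
    smooth_cutoff: float = 1.0,
) -> PoseTrace:
    """Interpolate low-confidence frames, resample, and smooth.

    Frames with confidence below ``min_conf`` are replaced by linear
    interpolation of their confident neighbors; the trace is then
    resampled to ``target_fs`` by linear interpolation on the time grid
    and low-pass smoothed (zero-phase Butterworth) when the cutoff is
    below the new Nyquist frequency.
    """
    good = pose.confidence >= min_conf
    if good.sum() < 2:
        raise ValueError("need at least two frames above the confidence threshold")
    n = len(pose.x)
    t = np.arange(n) / pose.fs
    x = np.interp(t, t[good], pose.x[good])
    y = np.interp(t, t[good], pose.y[good])

    duration = (n - 1) / pose.fs
    n_out = int(np.floor(duration * target_fs)) + 1
    t_out = np.arange(n_out) / target_fs
    x_out = np.interp(t_out, t, x)
    y_out = np.interp(t_out, t, y)

    if 0 < smooth_cutoff < target_fs / 2 and n_out > 12:
        sos = _signal.butter(2, smooth_cutoff, btype="low", fs=target_fs, output="sos")
        x_out = _signal.sosfiltfilt(sos, x_out)
        y_out = _signal.sosfiltfilt(sos, y_out)

    conf = np.ones(n_out)
    return PoseTrace(x=x_out, y=y_out, confidence=conf, fs=target_fs)
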