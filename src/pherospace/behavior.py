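"""Behavioral spatial statistics.

Analyses of freely moving fly pairs (a mobile "receiver" and a stationary
or mobile "stimulus" fly) and of tethered flies on a spherical treadmill:

* opposite-sex preference (OSP) — percentage of time spent near an
  opposite-sex vs a same-sex stimulus;
* turn-initiation detection with gates on angular velocity, sensation
  range and recent physical contact, and the relative orientation of the
  stimulus at turn onset;
* circular statistics (vector median, nonparametric common-median test);
* treadmill trial classification and signed lateral displacement with a
  permutation test.

World coordinates are standard (x east, y north, orientations in degrees
counter-clockwise from +x). Egocentric angles are positive to the
*receiver's right*: a stimulus 90° clockwise of the heading has relative
orientation +90°.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TrackedPair",
    "OSPResult",
    "TurnEvent",
    "CircularSample",
    "TreadmillTrial",
    "clean_tracks",
    "osp_score",
    "detect_turns",
    "relative_orientation",
    "circular_median",
    "circular_median_test",
    "classify_treadmill_trial",
    "lateral_displacement",
    "displacement_permutation_test",
]

# keypoint offsets synthesized from centroid + orientation when a tracker
# provides no body-part keypoints (mm along the heading axis)
ANTENNAE_OFFSET_MM = 1.2
ABDOMEN_OFFSET_MM = 1.2
BALL_RADIUS_MM = 4.5  # spherical treadmill: 9 mm diameter ball


def _wrap_deg(a):
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return w if w.ndim else float(w)


@dataclass
class TrackedPair:
    """Synchronized receiver and stimulus tracks in arena coordinates."""

    fs: float
    receiver_x: np.ndarray
    receiver_y: np.ndarray
    receiver_orientation: np.ndarray  # deg, CCW from +x
    stimulus_x: np.ndarray
    stimulus_y: np.ndarray
    stimulus_orientation: np.ndarray
    arena_center: tuple[float, float] = (0.0, 0.0)
    arena_radius: float = 8.0  # mm
    valid: np.ndarray | None = None

    def __post_init__(self):
        arrays = [
            "receiver_x", "receiver_y", "receiver_orientation",
            "stimulus_x", "stimulus_y", "stimulus_orientation",
        ]
        n = None
        for name in arrays:
            a = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, a)
            if n is None:
                n = len(a)
            elif len(a) != n:
                raise ValueError("all track arrays must share a length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.receiver_x)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def centroid_distance(self) -> np.ndarray:
        return np.hypot(self.receiver_x - self.stimulus_x,
                        self.receiver_y - self.stimulus_y)

    def receiver_antennae(self) -> tuple[np.ndarray, np.ndarray]:
        """Antennae keypoint: centroid + 1.2 mm along the heading."""
        th = np.radians(self.receiver_orientation)
        return (self.receiver_x + ANTENNAE_OFFSET_MM * np.cos(th),
                self.receiver_y + ANTENNAE_OFFSET_MM * np.sin(th))

    def stimulus_abdomen(self) -> tuple[np.ndarray, np.ndarray]:
        """Abdomen keypoint: centroid − 1.2 mm along the heading."""
        th = np.radians(self.stimulus_orientation)
        return (self.stimulus_x - ABDOMEN_OFFSET_MM * np.cos(th),
                self.stimulus_y - ABDOMEN_OFFSET_MM * np.sin(th))

    def antennae_abdomen_distance(self) -> np.ndarray:
        ax, ay = self.receiver_antennae()
        bx, by = self.stimulus_abdomen()
        return np.hypot(ax - bx, ay - by)

    def wall_distance(self) -> np.ndarray:
        cx, cy = self.arena_center
        r = np.hypot(self.receiver_x - cx, self.receiver_y - cy)
        return self.arena_radius - r


@dataclass(frozen=True)
class OSPResult:
    """Opposite-sex preference score and distance profiles."""

    osp: float  # percent, in [-100, 100]
    radius: float  # mm
    cumulative_profile: dict  # radius mm -> OSP within that radius
    discrete_profile: dict  # (r, r+1) mm bin -> OSP in that bin

    def __post_init__(self):
        if not -100.0 <= self.osp <= 100.0:
            raise ValueError("OSP must lie in [-100, 100]")


@dataclass(frozen=True)
class TurnEvent:
    """A detected turn initiation."""

    frame: int
    time_s: float
    rel_orientation_deg: float  # stimulus bearing in receiver frame at onset
    angular_velocity_dps: float


@dataclass(frozen=True)
class CircularSample:
    """A set of directions in degrees."""

    angles_deg: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "angles_deg",
                           np.asarray(self.angles_deg, dtype=float))
        if len(self.angles_deg) == 0:
            raise ValueError("empty circular sample")

    @property
    def median_deg(self) -> float:
        return circular_median(self)


@dataclass
class TreadmillTrial:
    """Velocity traces of a tethered fly on a spherical treadmill."""

    forward: np.ndarray  # mm/s, + forward
    lateral: np.ndarray  # mm/s, + toward the fly's right
    rotational: np.ndarray  # deg/s, + turning right (clockwise from above)
    fs: float = 50.0
    stim_side: str = "right"  # side of male presentation
    stim_window: tuple[float, float] = (2.0, 5.0)  # s
    ball_radius: float = BALL_RADIUS_MM

    def __post_init__(self):
        for name in ("forward", "lateral", "rotational"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.forward) == len(self.lateral) == len(self.rotational)):
            raise ValueError("velocity traces must share a length")
        if self.stim_side not in ("left", "right"):
            raise ValueError("stim_side must be 'left' or 'right'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.forward)) / self.fs

    def rotational_mm(self) -> np.ndarray:
        """Rotational speed expressed as rim speed in mm/s."""
        return np.radians(self.rotational) * self.ball_radius

    def speed(self) -> np.ndarray:
        """Three-axis speed magnitude, mm/s."""
        return np.sqrt(self.forward**2 + self.lateral**2 + self.rotational_mm()**2)


# ---------------------------------------------------------------------------
# track cleaning and OSP


def clean_tracks(pair: TrackedPair,
                 max_speed: float = 25.0,
                 max_turn_rate: float = 400.0) -> TrackedPair:
    """Mark tracking-glitch frames invalid.

    A frame is removed when the receiver's centroid velocity exceeds
    ``max_speed`` (mm/s) or its orientation changes faster than
    ``max_turn_rate`` (deg/s). Offending frames are excluded from all
    downstream statistics; no interpolation is performed.
    """
    if len(pair) < 2:
        raise ValueError("need at least two frames")
    vx = np.diff(pair.receiver_x) * pair.fs
    vy = np.diff(pair.receiver_y) * pair.fs
    speed = np.hypot(vx, vy)
    dori = np.abs(_wrap_deg(np.diff(pair.receiver_orientation))) * pair.fs
    bad_step = (speed > max_speed) | (dori > max_turn_rate)
    valid = pair.valid.copy()
    valid[1:][bad_step] = False  # the frame that jumped
    if not valid.any():
        raise ValueError("all frames invalid after cleaning")
    return replace(pair, valid=valid)


def _near_time(pair: TrackedPair, radius: float, rim_margin: float) -> float:
    """Seconds spent within ``radius`` of the stimulus, rim frames excluded."""
    ok = pair.valid & (pair.wall_distance() >= rim_margin)
    near = ok & (pair.centroid_distance() <= radius)
    return float(near.sum()) / pair.fs


def osp_score(traj_opposite: TrackedPair,
              traj_same: TrackedPair,
              radius: float = 5.0,
              rim_margin: float = 2.0,
              max_profile_radius: float = 12.0) -> OSPResult:
    """Opposite-sex preference.

    OSP = (time within ``radius`` of the opposite-sex stimulus − time
    within ``radius`` of the same-sex stimulus) / total assay time × 100.
    Frames closer than ``rim_margin`` to the arena wall are excluded
    (tracking is unreliable there). Profiles are reported for cumulative
    radii 1, 2, … mm and for discrete 1-mm annuli.
    """
    T_opp = len(traj_opposite) / traj_opposite.fs
    T_same = len(traj_same) / traj_same.fs
    if abs(T_opp - T_same) > 0.05 * max(T_opp, T_same):
        raise ValueError("assay durations differ by more than 5%")
    T = T_opp

    def score(r):
        return ((_near_time(traj_opposite, r, rim_margin)
                 - _near_time(traj_same, r, rim_margin)) / T * 100.0)

    radii = np.arange(1.0, max_profile_radius + 1e-9)
    cumulative = {float(r): score(r) for r in radii}
    discrete = {}
    prev = 0.0
    for r in radii:
        cur = cumulative[float(r)]
        discrete[(float(r - 1), float(r))] = cur - prev
        prev = cur
    return OSPResult(osp=score(radius), radius=radius,
                     cumulative_profile=cumulative, discrete_profile=discrete)


# ---------------------------------------------------------------------------
# turns and relative orientation


def relative_orientation(pair: TrackedPair, frame: int) -> float:
    """Stimulus bearing in the receiver's egocentric frame, degrees.

    0° is directly ahead; positive angles are to the receiver's *right*;
    wrapped to (−180°, 180°].
    """
    dx = pair.stimulus_x[frame] - pair.receiver_x[frame]
    dy = pair.stimulus_y[frame] - pair.receiver_y[frame]
    if dx == 0 and dy == 0:
        raise ValueError("receiver and stimulus positions coincide")
    bearing = math.degrees(math.atan2(dy, dx))
    # world angles are CCW-positive; egocentric right is clockwise of the
    # heading, hence the sign flip
    return float(_wrap_deg(-(bearing - pair.receiver_orientation[frame])))


def angular_velocity(pair: TrackedPair) -> np.ndarray:
    """Receiver angular velocity (deg/s) from the unwrapped orientation,
    central differences, same length as the track."""
    ori = np.degrees(np.unwrap(np.radians(pair.receiver_orientation)))
    return np.gradient(ori) * pair.fs


def detect_turns(pair: TrackedPair,
                 vel_thresh: float = 60.0,
                 min_gap: float = 1.0,
                 range_outer: float = 5.0,
                 range_inner: float = 2.0,
                 contact_cooloff: float = 30.0,
                 outlier_sd: float = 3.0,
                 clean: bool = True) -> list[TurnEvent]:
    """Detect turn initiations subject to the sensation-range gates.

    A turn starts when the absolute angular velocity rises above
    ``vel_thresh`` (deg/s); onsets closer than ``min_gap`` seconds to the
    previous onset are merged into it. An onset is kept only when the
    stimulus is in sensation range — receiver antennae to stimulus
    abdomen closer than ``range_outer`` mm *and* centroids farther than
    ``range_inner`` mm — and not within ``contact_cooloff`` seconds after
    a close-contact episode (centroid distance below ``range_inner``).
    Finally, turns whose change in facing angle sits more than
    ``outlier_sd`` standard deviations off the regression of facing-angle
    change on angular velocity are discarded.
    """
    if clean:
        pair = clean_tracks(pair)
    omega = angular_velocity(pair)
    fast = (np.abs(omega) > vel_thresh) & pair.valid
    onsets = np.nonzero(fast & ~np.roll(fast, 1))[0]
    if len(onsets) and fast[0] and onsets[0] != 0:
        onsets = np.concatenate([[0], onsets])

    # merge onsets separated by less than min_gap into the first
    merged: list[int] = []
    for i in onsets:
        if merged and (i - merged[-1]) / pair.fs < min_gap:
            continue
        merged.append(int(i))

    cen = pair.centroid_distance()
    ant_abd = pair.antennae_abdomen_distance()
    in_contact = cen < range_inner
    # cool-off: frames during contact and for contact_cooloff s after it ends
    cooloff = in_contact.copy()
    cool_frames = int(round(contact_cooloff * pair.fs))
    ends = np.nonzero(in_contact[:-1] & ~in_contact[1:])[0]
    for e in ends:
        cooloff[e + 1:e + 1 + cool_frames] = True

    events: list[TurnEvent] = []
    deltas: list[float] = []
    ori = np.degrees(np.unwrap(np.radians(pair.receiver_orientation)))
    n = len(pair)
    for i in merged:
        if not (ant_abd[i] < range_outer and cen[i] > range_inner):
            continue
        if cooloff[i]:
            continue
        j = i
        while j + 1 < n and abs(omega[j + 1]) > vel_thresh:
            j += 1
        deltas.append(abs(ori[min(j + 1, n - 1)] - ori[i]))
        events.append(TurnEvent(
            frame=i,
            time_s=i / pair.fs,
            rel_orientation_deg=relative_orientation(pair, i),
            angular_velocity_dps=float(omega[i]),
        ))

    # outlier rule: |Δfacing| regressed on |angular velocity| across events
    if len(events) >= 3:
        x = np.array([abs(e.angular_velocity_dps) for e in events])
        y = np.array(deltas)
        if np.var(x) > 0:
            A = np.column_stack([x, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            sd = resid.std(ddof=1)
            if sd > 0:
                keep = np.abs(resid) <= outlier_sd * sd
                events = [e for e, k in zip(events, keep) if k]
    return events


# ---------------------------------------------------------------------------
# circular statistics


def _circ_dist_deg(a, b):
    """Circular distance in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a)[..., None] - np.asarray(b)[None, ...]) % 360.0
    return np.minimum(d, 360.0 - d)


def _circ_mean_deg(angles: np.ndarray) -> float:
    th = np.radians(angles)
    return float(np.degrees(np.arctan2(np.sin(th).mean(), np.cos(th).mean())))


def circular_median(sample: "CircularSample | np.ndarray") -> float:
    """Vector (circular) median: the direction minimizing the summed
    circular distance to the sample, ties broken toward the circular
    mean. Returned in (−180°, 180°]."""
    angles = sample.angles_deg if isinstance(sample, CircularSample) else \
        np.asarray(sample, dtype=float)
    if len(angles) == 0:
        raise ValueError("empty sample")
    a = np.sort(np.mod(angles, 360.0))
    # candidate minimizers: the data points and the circular midpoints of
    # adjacent sorted points (the minimum of the objective is attained on
    # one of these for any sample)
    mids = np.mod(a + np.diff(np.concatenate([a, [a[0] + 360.0]])) / 2.0, 360.0)
    cands = np.concatenate([a, mids])
    sums = _circ_dist_deg(cands, a).sum(axis=1)
    best = sums.min()
    tied = cands[sums <= best + 1e-9]
    mean = _circ_mean_deg(angles)
    winner = tied[np.argmin(_circ_dist_deg(tied, np.array([mean]))[:, 0])]
    return float(_wrap_deg(winner))


def circular_median_test(*groups, method: str = "auto",
                         n_perm: int = 999, seed: int | None = None) -> dict:
    """Nonparametric test for a common circular median across groups
    (Fisher's common-median test, a circular analogue of a rank-based
    multi-sample location test).

    For the pooled circular median M, the test compares the per-group
    counts of observations on one side of the diameter through M against
    their expectation. ``method='auto'`` uses the exact hypergeometric
    (Fisher's exact) p-value for two groups — the margins are fixed by
    the pooled-median construction — and the asymptotic chi-square with
    (k−1) degrees of freedom otherwise; ``'chi2'`` forces the asymptotic
    form and ``'permutation'`` recomputes the statistic under random
    relabelings.
    """
    groups = [g.angles_deg if isinstance(g, CircularSample)
              else np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 5 for g in groups):
        raise ValueError("need at least five angles per group")
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    N = len(pooled)

    def statistic(parts):
        M = circular_median(np.concatenate(parts))
        m = np.array([np.sum(np.sin(np.radians(g - M)) > 0) for g in parts],
                     dtype=float)
        Mtot = m.sum()
        if Mtot == 0 or Mtot == N:
            return 0.0
        return (N**2 / (Mtot * (N - Mtot)) * np.sum(m**2 / sizes)
                - N * Mtot / (N - Mtot))

    stat = statistic(groups)
    k = len(groups)
    if method == "auto":
        method = "exact" if k == 2 else "chi2"
    if method == "exact":
        if k != 2:
            raise ValueError("the exact form is defined for two groups")
        M = circular_median(pooled)
        m = [int(np.sum(np.sin(np.radians(g - M)) > 0)) for g in groups]
        table = [[m[0], len(groups[0]) - m[0]], [m[1], len(groups[1]) - m[1]]]
        p = float(_stats.fisher_exact(table)[1])
    elif method == "chi2":
        p = float(_stats.chi2.sf(stat, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if statistic(parts) >= stat - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"test": "common circular median", "method": method,
            "statistic": float(stat), "p_value": p, "df": k - 1,
            "medians": [circular_median(g) for g in groups]}


# ---------------------------------------------------------------------------
# treadmill


def classify_treadmill_trial(trial: TreadmillTrial,
                             no_move_thresh: float = 0.75,
                             rest_thresh: float = 0.25,
                             pre_window: float = 1.0) -> str:
    """Classify a treadmill trial as ``no_movement``, ``constant_movement``
    or ``valid``.

    * ``no_movement``: the 95th percentile of the speed along each of the
      three axes stays below 0.75 mm/s for the whole trial.
    * ``constant_movement``: the three-axis speed never drops below
      0.25 mm/s in the window from ``pre_window`` s before stimulus onset
      to stimulus offset.
    * otherwise ``valid``.
    """
    axes = [np.abs(trial.forward), np.abs(trial.lateral),
            np.abs(trial.rotational_mm())]
    if all(np.percentile(a, 95) < no_move_thresh for a in axes):
        return "no_movement"
    t = trial.times
    lo = trial.stim_window[0] - pre_window
    hi = trial.stim_window[1]
    win = (t >= lo) & (t <= hi)
    if not win.any():
        raise ValueError("trial does not cover the peristimulus window")
    if np.min(trial.speed()[win]) >= rest_thresh:
        return "constant_movement"
    return "valid"


def movement_onset(trial: TreadmillTrial, rest_thresh: float = 0.25,
                   pre_window: float = 1.0) -> int:
    """First frame in the peristimulus window where the three-axis speed
    rises above ``rest_thresh`` mm/s out of a quiescent frame."""
    s = trial.speed()
    t = trial.times
    lo = trial.stim_window[0] - pre_window
    hi = trial.stim_window[1]
    moving = s >= rest_thresh
    for i in np.nonzero((t >= lo) & (t <= hi))[0]:
        if moving[i] and (i == 0 or not moving[i - 1]):
            return int(i)
    raise ValueError("no movement onset found in the peristimulus window")


def lateral_displacement(trial: TreadmillTrial, window: float = 1.0,
                         rest_thresh: float = 0.25) -> float:
    """Signed lateral displacement (mm) in the first second after
    movement onset, positive toward the stimulus side.

    The fly's fictive path is dead-reckoned: the heading accumulates the
    rotational velocity, and the forward and lateral velocities are
    projected through it, so that rotation followed by forward running
    contributes to lateral displacement.
    """
    i0 = movement_onset(trial, rest_thresh=rest_thresh)
    n = min(len(trial.forward), i0 + int(round(window * trial.fs)))
    dt = 1.0 / trial.fs
    psi = 0.0  # heading change, deg; + = turned right
    x = 0.0  # lateral world displacement, + = fly's initial right
    for i in range(i0, n):
        psi += trial.rotational[i] * dt
        r = math.radians(psi)
        x += (trial.forward[i] * math.sin(r) + trial.lateral[i] * math.cos(r)) * dt
    return x if trial.stim_side == "right" else -x


def displacement_permutation_test(left_trials, right_trials,
                                  n_perm: int = 10_000,
                                  seed: int | None = None,
                                  exact_limit: int = 20_000) -> dict:
    """Two-sided permutation test for a difference in mean lateral
    displacement between left- and right-presentation trials.

    Enumerates all reassignments exactly when their number is at most
    ``exact_limit``; otherwise uses ``n_perm`` Monte-Carlo permutations
    with the add-one p-value correction.
    """
    a = np.asarray(left_trials, dtype=float)
    b = np.asarray(right_trials, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least three trials per side")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    n_comb = math.comb(n, na)
    tol = 1e-12
    if n_comb <= exact_limit:
        count = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, na):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            t = pooled[sel].mean() - pooled[~sel].mean()
            if abs(t) >= abs(obs) - tol:
                count += 1
        p = count / n_comb
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            t = perm[:na].mean() - perm[na:].mean()
            if abs(t) >= abs(obs) - tol:
                count += 1
        p = (count + 1) / (n_perm + 1)
        method = "monte-carlo"
    return {"test": "permutation (mean difference)", "method": method,
            "statistic": float(obs), "p_value": float(p),
            "n_left": int(na), "n_right": int(len(b))}
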