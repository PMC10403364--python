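"""Synthetic data generation with known ground truth.

Every input the analysis pipeline consumes can be generated here: calcium
traces from a forward model of bilateral pheromone sensing, hexagonal
lattice sessions, arena trajectories, scripted turn scenarios, treadmill
trials and toy synapse tables. All generators are deterministic under a
fixed seed.

The forward model
-----------------
The instantaneous receptor drive at an antenna is a logistic function of
the distance d (mm) from the male's abdomen to that antenna:

    R(d) = base + (top − base) / (1 + exp((d − ed50) / slope))

— the same sigmoid-in-distance form that the imaging analyses fit. The
drive is convolved with a first-order calcium kernel (time constant
``tau_rise``) and i.i.d. Gaussian noise is added per sample. A bilateral
projection-neuron (PN) stage combines the two antennae linearly,

    PN_side = w_ipsi·ORN_same + w_contra·ORN_other − g_inhib·ORN_other,

clipped at zero: ``w_contra`` is direct contralateral excitation (ORN
axons cross the midline) and ``g_inhib`` is contralateral inhibition
relayed by a commissural local interneuron driven by the opposite
antenna. When the *net* contralateral influence is inhibitory
(``g_inhib > w_contra`` with ``w_ipsi = 1``) the PN stage amplifies the
bilateral contrast relative to the receptor stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .behavior import TrackedPair, TreadmillTrial
from .spatial import SQRT3, BilateralResponse, HexLattice, wrap_angle_deg
from .traces import DffTrace

__all__ = [
    "ForwardModelParams",
    "StimulusScript",
    "ScriptedTurn",
    "ToyConnectomeSpec",
    "PRINTED_DISTANCES",
    "PRESENTATION_SPEEDS",
    "logistic_response",
    "simulate_orn_trace",
    "simulate_bilateral_pn",
    "steady_state_orn",
    "steady_state_pn",
    "generate_lattice_session",
    "generate_osp_trajectories",
    "generate_turn_scenario",
    "generate_treadmill_trial",
    "generate_toy_connectome",
    "default_toy_connectome_spec",
]

# the ten presentation distances of the distance-tuning protocol (mm)
PRINTED_DISTANCES = (5.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.75, 0.5, 0.25)
# male approach speeds of the speed-tuning protocol (mm/s)
PRESENTATION_SPEEDS = (1.41, 4.30, 8.04)

# bilateral weight ratio from the connectome synapse counts:
# ipsilateral ORN→lPN 5184, contralateral ORN→lPN 3580
_W_CONTRA_DEFAULT = 3580.0 / 5184.0


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the bilateral forward model.

    top, base : dimensionless
        Near-field maximum and far-field asymptote of the normalized
        response.
    ed50 : mm
        Half-maximal distance of the logistic distance tuning.
    slope : mm
        Logistic scale; smaller is steeper.
    w_ipsi, w_contra : dimensionless
        Excitatory weights of the same-side and opposite-side antenna on
        a PN. The default ratio follows the ipsi/contra ORN→lPN synapse
        counts (5184 : 3580).
    g_inhib : dimensionless
        Gain of contralateral inhibition (commissural interneuron driven
        by the opposite antenna). Contrast amplification requires
        ``w_ipsi − w_contra + g_inhib > 1``.
    tau_rise : s
        First-order calcium kernel time constant.
    noise_sd : ΔF/F units
        Per-sample Gaussian noise.
    antenna_sep : mm
        Inter-antennal distance; antennae sit at (0, ±antenna_sep/2) in
        receiver coordinates (x frontal, y rightward).
    front_mod : dimensionless
        Front-to-back modulation of the summed bilateral response (the
        receiver's body occludes stimuli behind it); drives the cosine
        component of the bilateral sum in lattice sessions.
    """

    top: float = 1.0
    base: float = 0.05
    ed50: float = 2.4
    slope: float = 0.5
    w_ipsi: float = 1.0
    w_contra: float = _W_CONTRA_DEFAULT
    g_inhib: float = 1.0
    tau_rise: float = 0.3
    noise_sd: float = 0.05
    antenna_sep: float = 0.3
    front_mod: float = 0.25

    def __post_init__(self):
        if not self.top > self.base >= 0:
            raise ValueError("require top > base >= 0")
        if self.ed50 <= 0 or self.slope <= 0:
            raise ValueError("ed50 and slope must be positive")
        if not self.w_ipsi >= self.w_contra >= 0:
            raise ValueError("require w_ipsi >= w_contra >= 0")
        if self.g_inhib < 0 or self.antenna_sep <= 0:
            raise ValueError("g_inhib must be >= 0 and antenna_sep > 0")


def logistic_response(d, params: ForwardModelParams):
    """Steady-state receptor drive at distance ``d`` (mm)."""
    d = np.asarray(d, dtype=float)
    # expit(-z) = 1/(1+exp(z)) without overflow at large distances
    out = params.base + (params.top - params.base) * expit(
        -(d - params.ed50) / params.slope)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class StimulusScript:
    """Piecewise-linear male trajectory in receiver coordinates.

    ``waypoints`` is an ordered list of (time s, (x mm, y mm)); the
    position is linearly interpolated between waypoints and held constant
    outside them. ``epochs`` optionally annotates (t_on, t_off, label)
    presentation windows.
    """

    waypoints: tuple
    epochs: tuple = ()

    def __post_init__(self):
        times = [t for t, _ in self.waypoints]
        if len(times) < 1:
            raise ValueError("need at least one waypoint")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("waypoint times must be strictly increasing")
        for _, (x, y) in self.waypoints:
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError("non-finite stimulus position")

    @property
    def duration(self) -> float:
        return float(self.waypoints[-1][0])

    def positions(self, t) -> np.ndarray:
        """(n, 2) male positions at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        wt = np.array([w[0] for w in self.waypoints])
        wx = np.array([w[1][0] for w in self.waypoints])
        wy = np.array([w[1][1] for w in self.waypoints])
        return np.column_stack([np.interp(t, wt, wx), np.interp(t, wt, wy)])

    @classmethod
    def hold(cls, position, duration: float, start: float = 0.0) -> "StimulusScript":
        return cls(waypoints=((start, tuple(position)),
                              (start + duration, tuple(position))),
                   epochs=((start, start + duration, "hold"),))

    @classmethod
    def distance_protocol(cls, distances=PRINTED_DISTANCES, hold_s: float = 5.0,
                          inter_s: float = 12.0, far_mm: float = 10.0,
                          move_speed: float = 8.0) -> "StimulusScript":
        """The distance-tuning presentation protocol: from a far resting
        position the male approaches each test distance frontally, holds
        ~5 s, and retreats for ~12 s between presentations."""
        wp = []
        ep = []
        t = 0.0
        wp.append((t, (far_mm, 0.0)))
        for d in distances:
            travel = abs(far_mm - d) / move_speed
            t += travel
            wp.append((t, (d, 0.0)))
            ep.append((t, t + hold_s, float(d)))
            t += hold_s
            wp.append((t, (d, 0.0)))
            t += travel
            wp.append((t, (far_mm, 0.0)))
            t += inter_s
            wp.append((t, (far_mm, 0.0)))
        return cls(waypoints=tuple(wp), epochs=tuple(ep))

    @classmethod
    def approach(cls, speed: float, start_mm: float = 5.0,
                 stop_mm: float = 0.5, hold_s: float = 3.0) -> "StimulusScript":
        """Frontal approach at constant speed, then hold."""
        if speed <= 0:
            raise ValueError("speed must be positive")
        travel = (start_mm - stop_mm) / speed
        wp = ((0.0, (start_mm, 0.0)), (travel, (stop_mm, 0.0)),
              (travel + hold_s, (stop_mm, 0.0)))
        return cls(waypoints=wp, epochs=((0.0, travel + hold_s, speed),))

    @classmethod
    def lateral_presentation(cls, side: str, duration: float = 5.0,
                             frontal_mm: float = 0.5,
                             lateral_mm: float = 1.25) -> "StimulusScript":
        """Static presentation 1.25 mm to one side of the antennae."""
        y = lateral_mm if side == "right" else -lateral_mm
        return cls.hold((frontal_mm, y), duration)


def _antenna_position(params: ForwardModelParams, antenna: str) -> np.ndarray:
    half = params.antenna_sep / 2.0
    if antenna == "left":
        return np.array([0.0, -half])
    if antenna == "right":
        return np.array([0.0, half])
    if antenna in ("center", "none"):
        return np.array([0.0, 0.0])
    raise ValueError(f"unknown antenna {antenna!r}")


def _first_order_kernel(drive: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """Causal first-order low-pass (exponential approach to the drive)."""
    if tau <= 0:
        return drive
    a = 1.0 - math.exp(-1.0 / (fs * tau))
    y, _ = lfilter([a], [1.0, -(1.0 - a)], drive,
                   zi=np.array([(1.0 - a) * drive[0]]))
    return y


def simulate_orn_trace(params: ForwardModelParams, script: StimulusScript,
                       antenna: str = "left", fs: float = 7.2,
                       seed: int | None = None) -> DffTrace:
    """Simulate the ΔF/F trace of one antenna's receptor neurons.

    The noiseless trace at a constant distance converges to the logistic
    steady state R(d) within a few ``tau_rise``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(script.duration * fs)) + 1
    t = np.arange(n) / fs
    pos = script.positions(t)
    ant = _antenna_position(params, antenna)
    d = np.hypot(pos[:, 0] - ant[0], pos[:, 1] - ant[1])
    drive = logistic_response(d, params)
    y = _first_order_kernel(drive, fs, params.tau_rise)
    if params.noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, params.noise_sd, n)
    on, off = (script.epochs[0][0], script.epochs[-1][1]) if script.epochs \
        else (0.0, script.duration)
    return DffTrace(samples=y, fs=fs, stim_onset=on, stim_offset=off,
                    side=antenna if antenna in ("left", "right") else "none")


def steady_state_orn(params: ForwardModelParams, male_pos, antenna: str) -> float:
    ant = _antenna_position(params, antenna)
    d = math.hypot(male_pos[0] - ant[0], male_pos[1] - ant[1])
    return float(logistic_response(d, params))


def steady_state_pn(params: ForwardModelParams, male_pos,
                    clip: bool = True) -> tuple[float, float]:
    """Steady-state (left, right) PN responses to a static male."""
    ol = steady_state_orn(params, male_pos, "left")
    orr = steady_state_orn(params, male_pos, "right")
    pl = params.w_ipsi * ol + (params.w_contra - params.g_inhib) * orr
    pr = params.w_ipsi * orr + (params.w_contra - params.g_inhib) * ol
    if clip:
        pl, pr = max(pl, 0.0), max(pr, 0.0)
    return pl, pr


def simulate_bilateral_pn(params: ForwardModelParams, script: StimulusScript,
                          fs: float = 7.2, seed: int | None = None,
                          clip: bool = True, return_orn: bool = False):
    """Simulate the bilateral PN pair (left, right).

    Each PN combines same-side excitation, opposite-side excitation and
    opposite-side (interneuron-relayed) inhibition; the output is clipped
    at zero unless ``clip=False`` (exposing sustained suppression as a
    negative drive). With ``return_orn=True`` the underlying noiseless
    ORN traces are returned as well.
    """
    ss = np.random.SeedSequence(seed)
    s_l, s_r = ss.spawn(2)
    noiseless = replace(params, noise_sd=0.0)
    orn_l = simulate_orn_trace(noiseless, script, "left", fs)
    orn_r = simulate_orn_trace(noiseless, script, "right", fs)
    w_net_contra = params.w_contra - params.g_inhib
    pn_l = params.w_ipsi * orn_l.samples + w_net_contra * orn_r.samples
    pn_r = params.w_ipsi * orn_r.samples + w_net_contra * orn_l.samples
    if clip:
        pn_l = np.clip(pn_l, 0.0, None)
        pn_r = np.clip(pn_r, 0.0, None)
    if params.noise_sd > 0:
        pn_l = pn_l + np.random.default_rng(s_l).normal(0, params.noise_sd, len(pn_l))
        pn_r = pn_r + np.random.default_rng(s_r).normal(0, params.noise_sd, len(pn_r))
    left = replace(orn_l, samples=pn_l, side="left")
    right = replace(orn_r, samples=pn_r, side="right")
    if return_orn:
        return left, right, orn_l, orn_r
    return left, right


def _angular_code_amplitudes(params: ForwardModelParams, r_mid: float):
    """Sum/difference amplitudes of the idealized angular code at the
    middle lattice ring, derived from the distance-tuning parameters."""
    gain_sum = params.w_ipsi + params.w_contra - params.g_inhib
    if gain_sum <= 0:
        raise ValueError("net summed PN drive must be positive "
                         "(w_ipsi + w_contra - g_inhib > 0)")
    gain_diff = params.w_ipsi - params.w_contra + params.g_inhib
    half = params.antenna_sep / 2.0
    orn_diff = (logistic_response(r_mid - half, params)
                - logistic_response(r_mid + half, params))
    s0 = 2.0 * gain_sum * logistic_response(r_mid, params)
    d1 = gain_diff * orn_diff
    return s0, d1


def generate_lattice_session(params: ForwardModelParams, lattice: HexLattice,
                             n_flies: int = 8, n_trials: int = 3,
                             seed: int | None = None,
                             mode: str = "angular") -> list[BilateralResponse]:
    """Left/right peak response pairs for every fly × trial × position.

    ``mode='angular'`` (default) draws responses from an idealized
    sinusoidal bilateral code — sum = s0·(1 + front_mod·cosθ),
    diff = d1·sinθ, with amplitudes derived from the logistic tuning —
    which is the generative model of the angular decoding experiment.
    ``mode='biophysical'`` instead evaluates the per-antenna logistic +
    contralateral-inhibition circuit at every lattice position. Gaussian
    trial noise (``noise_sd``) is added to each side independently.
    """
    if n_flies < 1 or n_trials < 1:
        raise ValueError("n_flies and n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    theta = np.radians(lattice.angles_deg)
    if mode == "angular":
        s0, d1 = _angular_code_amplitudes(params, SQRT3 * lattice.spacing)
        total = s0 * (1.0 + params.front_mod * np.cos(theta))
        diff = d1 * np.sin(theta)
        left = (total - diff) / 2.0
        right = (total + diff) / 2.0
    elif mode == "biophysical":
        lr = np.array([steady_state_pn(params, p) for p in lattice.positions])
        left, right = lr[:, 0], lr[:, 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out: list[BilateralResponse] = []
    for fly in range(n_flies):
        for trial in range(n_trials):
            for p in range(len(lattice)):
                nl = rng.normal(0, params.noise_sd) if params.noise_sd > 0 else 0.0
                nr = rng.normal(0, params.noise_sd) if params.noise_sd > 0 else 0.0
                out.append(BilateralResponse(
                    fly_id=fly, trial=trial, pos_index=p,
                    left=float(left[p] + nl), right=float(right[p] + nr)))
    return out


# ---------------------------------------------------------------------------
# behavioral generators


def generate_osp_trajectories(arena_radius: float = 8.0,
                              duration: float = 1200.0,
                              fs: float = 30.0,
                              attraction_bias: float = 0.0,
                              seed: int | None = None,
                              speed: float = 5.0,
                              turn_sd_deg: float = 30.0) -> TrackedPair:
    """Biased correlated random walk around a stationary stimulus fly.

    The stimulus sits 4 mm from the arena wall (waxed to the chamber
    floor); the receiver's heading change each frame mixes a Gaussian
    random turn with a turn toward the stimulus weighted by
    ``attraction_bias`` ∈ [0, 1]. The walk reflects off the wall.
    """
    if arena_radius <= 0:
        raise ValueError("arena_radius must be positive")
    if not 0.0 <= attraction_bias <= 1.0:
        raise ValueError("attraction_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    stim = np.array([arena_radius - 4.0, 0.0])
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)  # deg
    x[0], y[0] = -arena_radius / 2.0, 0.0
    heading[0] = rng.uniform(-180, 180)
    step = speed / fs
    b = attraction_bias
    for i in range(1, n):
        bearing = math.degrees(math.atan2(stim[1] - y[i - 1],
                                          stim[0] - x[i - 1]))
        err = wrap_angle_deg(bearing - heading[i - 1])
        turn = (1.0 - b) * rng.normal(0.0, turn_sd_deg) + b * 0.5 * err
        h = heading[i - 1] + turn
        nx = x[i - 1] + step * math.cos(math.radians(h))
        ny = y[i - 1] + step * math.sin(math.radians(h))
        if math.hypot(nx, ny) > arena_radius - 0.5:
            # reflect: turn toward the arena center with some scatter
            h = math.degrees(math.atan2(-y[i - 1], -x[i - 1])) \
                + rng.normal(0.0, 20.0)
            nx = x[i - 1] + step * math.cos(math.radians(h))
            ny = y[i - 1] + step * math.sin(math.radians(h))
        x[i], y[i], heading[i] = nx, ny, h
    return TrackedPair(
        fs=fs,
        receiver_x=x, receiver_y=y,
        receiver_orientation=wrap_angle_deg(heading),
        stimulus_x=np.full(n, stim[0]), stimulus_y=np.full(n, stim[1]),
        stimulus_orientation=np.zeros(n),
        arena_center=(0.0, 0.0), arena_radius=arena_radius)


@dataclass(frozen=True)
class ScriptedTurn:
    """One planted turn for :func:`generate_turn_scenario`."""

    time: float  # s, turn onset
    rel_orientation_deg: float = 0.0  # stimulus bearing in self frame at onset
    ang_speed_dps: float = 90.0
    magnitude_deg: float = 60.0
    distance_mm: float = 3.5  # receiver-stimulus centroid distance


def generate_turn_scenario(turns, fs: float = 30.0,
                           contact_episodes=(),
                           tail_s: float = 2.0,
                           setup_rate_dps: float = 30.0) -> TrackedPair:
    """A tracked pair with turns planted at known times and orientations.

    The stimulus is fixed at the origin facing away from the receiver;
    the receiver sits at the scripted centroid distance and rotates at
    the scripted angular speed at each turn time. Between turns the
    receiver repositions slowly (below the turn-detection threshold).
    ``contact_episodes`` is a list of (time, duration) during which the
    receiver approaches to 1.5 mm (a close-contact episode that should
    trigger the detector's cool-off gate).
    """
    turns = sorted(turns, key=lambda t: t.time)
    for t0, t1 in zip(turns, turns[1:]):
        if t1.time - t0.time < t0.magnitude_deg / t0.ang_speed_dps:
            raise ValueError("overlapping scripted turns")
    events = [("turn", t) for t in turns] + \
        [("contact", c) for c in contact_episodes]
    end_time = max(
        [t.time + t.magnitude_deg / t.ang_speed_dps for t in turns]
        + [c[0] + c[1] + 1.0 for c in contact_episodes] + [1.0]) + tail_s
    n = int(round(end_time * fs)) + 1
    tgrid = np.arange(n) / fs

    # bearing from receiver (at +x of the stimulus) to the stimulus is 180°
    bearing = 180.0
    dist = np.full(n, turns[0].distance_mm if turns else 3.5)
    ori = np.full(n, bearing + (turns[0].rel_orientation_deg if turns else 0.0))

    for t in turns:
        ori_pre = bearing + t.rel_orientation_deg
        i_on = int(round(t.time * fs))
        dur = t.magnitude_deg / t.ang_speed_dps
        i_off = int(round((t.time + dur) * fs))
        # slow setup toward ori_pre and the scripted distance before onset
        need = abs(wrap_angle_deg(ori_pre - ori[max(i_on - 1, 0)]))
        setup = max(need / setup_rate_dps, 0.3)
        i_setup = max(int(round((t.time - setup) * fs)), 0)
        ori[i_setup:i_on] = np.linspace(ori[max(i_setup - 1, 0)], ori_pre,
                                        max(i_on - i_setup, 1))
        dist[i_setup:i_on] = np.linspace(dist[max(i_setup - 1, 0)],
                                         t.distance_mm,
                                         max(i_on - i_setup, 1))
        ori[i_on:i_off + 1] = ori_pre + t.ang_speed_dps * (
            tgrid[i_on:i_off + 1] - tgrid[i_on])
        ori[i_off + 1:] = ori_pre + t.magnitude_deg
        dist[i_on:] = t.distance_mm

    for t0, dur in contact_episodes:
        i0 = int(round(t0 * fs))
        i1 = int(round((t0 + dur) * fs))
        ramp = max(int(round(0.5 * fs)), 1)
        prev = dist[max(i0 - ramp - 1, 0)]
        dist[i0 - ramp:i0] = np.linspace(prev, 1.5, ramp)
        dist[i0:i1] = 1.5
        back = min(i1 + ramp, n)
        dist[i1:back] = np.linspace(1.5, prev, back - i1)
        dist[back:] = np.maximum(dist[back:], prev)

    return TrackedPair(
        fs=fs,
        receiver_x=dist, receiver_y=np.zeros(n),
        receiver_orientation=wrap_angle_deg(ori),
        stimulus_x=np.zeros(n), stimulus_y=np.zeros(n),
        stimulus_orientation=np.full(n, 180.0),  # abdomen toward the receiver
        arena_center=(0.0, 0.0), arena_radius=8.0)


def generate_treadmill_trial(stim_side: str = "right",
                             response_lateral: float = 1.0,
                             response_rotation: float = 0.0,
                             onset_s: float = 2.5,
                             duration: float = 8.0,
                             fs: float = 50.0,
                             stim_window: tuple[float, float] = (2.0, 5.0),
                             noise_sd: float = 0.02,
                             seed: int | None = None) -> TreadmillTrial:
    """A treadmill trial: quiescence, then a 1-s movement bout starting at
    ``onset_s`` with the given lateral velocity (mm/s, + toward the
    stimulus side) and rotational velocity (deg/s)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    bout = (t >= onset_s) & (t < onset_s + 1.0)
    sign = 1.0 if stim_side == "right" else -1.0
    fwd = np.where(bout, 2.0, 0.0)
    lat = np.where(bout, sign * response_lateral, 0.0)
    rot = np.where(bout, sign * response_rotation, 0.0)
    if noise_sd > 0:
        fwd = fwd + rng.normal(0, noise_sd, n)
        lat = lat + rng.normal(0, noise_sd, n)
        rot = rot + rng.normal(0, noise_sd, n)
    return TreadmillTrial(forward=fwd, lateral=lat, rotational=rot, fs=fs,
                          stim_side=stim_side, stim_window=stim_window)


# ---------------------------------------------------------------------------
# toy connectome


@dataclass(frozen=True)
class ToyConnectomeSpec:
    """Specification of a toy synapse table.

    ``connections`` is a list of dicts with keys pre_type, post_type,
    side ('ipsi' | 'contra' | 'unknown'), roi, weight (total synapse
    count), and optionally n_pre / n_post (cell counts per type; the
    weight is split across cell pairs)."""

    connections: tuple
    seed: int = 0

    def __post_init__(self):
        for c in self.connections:
            if c["weight"] < 0 or int(c["weight"]) != c["weight"]:
                raise ValueError("synapse counts must be non-negative integers")
            if c["side"] not in ("ipsi", "contra", "unknown"):
                raise ValueError(f"bad side {c['side']!r}")


def generate_toy_connectome(spec: ToyConnectomeSpec) -> pd.DataFrame:
    """Expand a :class:`ToyConnectomeSpec` into a synapse table
    (neuprint-style export: pre_type, post_type, pre_id, post_id, roi,
    side, weight)."""
    rows = []
    ids: dict[str, int] = {}

    def cell_id(cell_type: str, i: int) -> int:
        key = f"{cell_type}:{i}"
        if key not in ids:
            ids[key] = 10_000 + len(ids)
        return ids[key]

    for c in spec.connections:
        n_pre = int(c.get("n_pre", 1))
        n_post = int(c.get("n_post", 1))
        pairs = [(i, j) for i in range(n_pre) for j in range(n_post)]
        w_total = int(c["weight"])
        base_w, rem = divmod(w_total, len(pairs))
        for k, (i, j) in enumerate(pairs):
            w = base_w + (1 if k < rem else 0)
            if w == 0:
                continue
            rows.append({
                "pre_type": c["pre_type"], "post_type": c["post_type"],
                "pre_id": cell_id(c["pre_type"], i),
                "post_id": cell_id(c["post_type"], j),
                "roi": c["roi"], "side": c["side"], "weight": w,
            })
    return pd.DataFrame(rows, columns=["pre_type", "post_type", "pre_id",
                                       "post_id", "roi", "side", "weight"])


def default_toy_connectome_spec() -> ToyConnectomeSpec:
    """A toy connectome with planted partner classes.

    Plants, downstream of the seed type ``DA1_lPN`` in the LH:

    * ``ON_included`` — 60 seed synapses (included irrespective of its
      0.1% relative input);
    * ``ON_excluded`` — 10 seed synapses (excluded: not more than 10);
    * ``ON_boundary_hi`` / ``ON_boundary_lo`` — 30 seed synapses at
      2.30% / 2.20% relative input, straddling the inclusion line;
    * input-selectivity fixtures ``TON_multi`` (sensory 30% of olfactory
      → multimodal), ``TON_da1`` (DA1 60% of olfactory → DA1-selective)
    and ``TON_mixed`` (DA1 40% → mixed-olfactory);
    * an ``il3LN6`` interneuron with the contra/ipsi ORN input counts of
      the DA1 glomerulus (1901 vs 359) plus two control glomeruli.
    """
    conns = [
        # partner-selection fixtures (inputs from the seed PN, in the LH)
        dict(pre_type="DA1_lPN", post_type="ON_included", side="ipsi",
             roi="LH", weight=60),
        dict(pre_type="OtherPN", post_type="ON_included", side="ipsi",
             roi="LH", weight=59_940),
        dict(pre_type="DA1_lPN", post_type="ON_excluded", side="ipsi",
             roi="LH", weight=10),
        dict(pre_type="OtherPN", post_type="ON_excluded", side="ipsi",
             roi="LH", weight=90),
        dict(pre_type="DA1_lPN", post_type="ON_boundary_hi", side="ipsi",
             roi="LH", weight=30),
        dict(pre_type="OtherPN", post_type="ON_boundary_hi", side="ipsi",
             roi="LH", weight=1274),  # 30/1304 = 2.30% > 2.25%
        dict(pre_type="DA1_lPN", post_type="ON_boundary_lo", side="ipsi",
             roi="LH", weight=30),
        dict(pre_type="OtherPN", post_type="ON_boundary_lo", side="ipsi",
             roi="LH", weight=1334),  # 30/1364 = 2.20% < 2.25%
        # input-selectivity fixtures
        dict(pre_type="DA1_lPN", post_type="TON_multi", side="ipsi",
             roi="LH", weight=60),
        dict(pre_type="DL3_PN", post_type="TON_multi", side="ipsi",
             roi="LH", weight=40),
        dict(pre_type="MechanoSensory", post_type="TON_multi", side="ipsi",
             roi="LH", weight=30),
        dict(pre_type="DA1_lPN", post_type="TON_da1", side="ipsi",
             roi="LH", weight=60),
        dict(pre_type="DL3_PN", post_type="TON_da1", side="ipsi",
             roi="LH", weight=40),
        dict(pre_type="MechanoSensory", post_type="TON_da1", side="ipsi",
             roi="LH", weight=10),
        dict(pre_type="DA1_lPN", post_type="TON_mixed", side="ipsi",
             roi="LH", weight=40),
        dict(pre_type="DL3_PN", post_type="TON_mixed", side="ipsi",
             roi="LH", weight=60),
        dict(pre_type="MechanoSensory", post_type="TON_mixed", side="ipsi",
             roi="LH", weight=10),
        # contra/ipsi interneuron profile (roi = glomerulus for AL records)
        dict(pre_type="ORN_DA1", post_type="il3LN6", side="contra",
             roi="DA1", weight=1901),
        dict(pre_type="ORN_DA1", post_type="il3LN6", side="ipsi",
             roi="DA1", weight=359),
        dict(pre_type="ORN_DL3", post_type="il3LN6", side="contra",
             roi="DL3", weight=400),
        dict(pre_type="ORN_DL3", post_type="il3LN6", side="ipsi",
             roi="DL3", weight=200),
        dict(pre_type="ORN_VA1v", post_type="il3LN6", side="unknown",
             roi="VA1v", weight=300),
        # interneuron outputs (for the output-fraction column)
        dict(pre_type="il3LN6", post_type="DA1_lPN", side="ipsi",
             roi="DA1", weight=465),
        dict(pre_type="il3LN6", post_type="LocalLN", side="ipsi",
             roi="DA1", weight=535),
        dict(pre_type="il3LN6", post_type="DL3_PN", side="ipsi",
             roi="DL3", weight=100),
        dict(pre_type="il3LN6", post_type="LocalLN", side="ipsi",
             roi="DL3", weight=300),
    ]
    return ToyConnectomeSpec(connections=tuple(conns))
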