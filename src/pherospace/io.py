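"""CSV readers/writers for the package's table formats.

All files are RFC-4180 CSV, UTF-8, '.' decimal:

* trace CSV: time_s, roi, side, dff
* bilateral-response CSV: fly_id, trial, pos_index, left, right
* trajectory CSV: frame, fly_id, x_mm, y_mm, orientation_deg
* treadmill CSV: frame, forward, lateral, rotational
* synapse CSV: pre_type, post_type, pre_id, post_id, roi, side, weight
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import TrackedPair, TreadmillTrial
from .spatial import BilateralResponse
from .traces import DffTrace

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_responses_csv", "read_responses_csv",
    "write_trajectory_csv", "read_trajectory_csv",
    "write_treadmill_csv", "read_treadmill_csv",
    "write_synapse_csv", "read_synapse_csv",
]


def write_trace_csv(path, traces: list[DffTrace]):
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.times, "roi": tr.roi_id, "side": tr.side,
            "dff": tr.samples}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_csv(path, fs: float, stim_onset: float,
                   stim_offset: float) -> list[DffTrace]:
    df = pd.read_csv(path)
    out = []
    for (roi, side), g in df.groupby(["roi", "side"], sort=False):
        g = g.sort_values("time_s")
        out.append(DffTrace(samples=g["dff"].to_numpy(), fs=fs,
                            stim_onset=stim_onset, stim_offset=stim_offset,
                            sweep_start=float(g["time_s"].iloc[0]),
                            roi_id=str(roi), side=str(side)))
    return out


def write_responses_csv(path, responses: list[BilateralResponse]):
    pd.DataFrame([{
        "fly_id": r.fly_id, "trial": r.trial, "pos_index": r.pos_index,
        "left": r.left, "right": r.right} for r in responses
    ]).to_csv(path, index=False)


def read_responses_csv(path) -> list[BilateralResponse]:
    df = pd.read_csv(path)
    return [BilateralResponse(fly_id=int(r.fly_id), trial=int(r.trial),
                              pos_index=int(r.pos_index),
                              left=float(r.left), right=float(r.right))
            for r in df.itertuples()]


def write_trajectory_csv(path, pair: TrackedPair):
    n = len(pair)
    df = pd.DataFrame({
        "frame": np.tile(np.arange(n), 2),
        "fly_id": np.repeat(["receiver", "stimulus"], n),
        "x_mm": np.concatenate([pair.receiver_x, pair.stimulus_x]),
        "y_mm": np.concatenate([pair.receiver_y, pair.stimulus_y]),
        "orientation_deg": np.concatenate([pair.receiver_orientation,
                                           pair.stimulus_orientation]),
    })
    df.to_csv(path, index=False)


def read_trajectory_csv(path, fs: float, arena_radius: float = 8.0) -> TrackedPair:
    df = pd.read_csv(path)
    rec = df[df.fly_id == "receiver"].sort_values("frame")
    stim = df[df.fly_id == "stimulus"].sort_values("frame")
    return TrackedPair(
        fs=fs,
        receiver_x=rec["x_mm"].to_numpy(),
        receiver_y=rec["y_mm"].to_numpy(),
        receiver_orientation=rec["orientation_deg"].to_numpy(),
        stimulus_x=stim["x_mm"].to_numpy(),
        stimulus_y=stim["y_mm"].to_numpy(),
        stimulus_orientation=stim["orientation_deg"].to_numpy(),
        arena_radius=arena_radius)


def write_treadmill_csv(path, trial: TreadmillTrial):
    pd.DataFrame({
        "frame": np.arange(len(trial.forward)),
        "forward": trial.forward, "lateral": trial.lateral,
        "rotational": trial.rotational}).to_csv(path, index=False)


def read_treadmill_csv(path, fs: float = 50.0, stim_side: str = "right",
                       stim_window=(2.0, 5.0)) -> TreadmillTrial:
    df = pd.read_csv(path).sort_values("frame")
    return TreadmillTrial(forward=df["forward"].to_numpy(),
                          lateral=df["lateral"].to_numpy(),
                          rotational=df["rotational"].to_numpy(),
                          fs=fs, stim_side=stim_side,
                          stim_window=tuple(stim_window))


def write_synapse_csv(path, table: pd.DataFrame):
    table.to_csv(path, index=False)


def read_synapse_csv(path) -> pd.DataFrame:
    from .connectome import validate_synapse_table
    return validate_synapse_table(pd.read_csv(path))
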