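"""End-to-end orchestration: configuration, validation, reporting.

A :class:`RunConfig` carries the single seed and the analysis parameters
(every threshold defaults to its standard value and is overridable);
:func:`run_pipeline` runs simulate → analyze → report deterministically
and returns a JSON-serializable report with the package version, a
config hash, and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .spatial import build_hex_lattice, cross_validate_decoder, sincos_regression, angular_tuning
from .synthetic import (ForwardModelParams, default_toy_connectome_spec,
                        generate_lattice_session, generate_toy_connectome,
                        PRINTED_DISTANCES)
from .tuning import TuningCurve, fit_sigmoid
from .connectome import contra_ipsi_profile, select_downstream_types

logger = logging.getLogger("pherospace")

__all__ = ["RunConfig", "run_pipeline", "validate_tables", "TABLE_SCHEMAS"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the standard analysis values."""

    seed: int = 0
    lattice_spacing: float = 1.0  # mm
    lattice_max_distance: float = 2.0  # mm
    n_flies: int = 8
    n_trials: int = 3
    noise_sd: float = 0.05  # trial noise, normalized ΔF/F units
    filter_cutoff_hz: float = 1.0
    turn_vel_thresh_dps: float = 60.0
    n_permutations: int = 10_000
    decoder_scheme: str = "loo-fly"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a lattice session, decode it, fit a distance-tuning
    sigmoid on forward-model data, and profile the toy connectome.

    All randomness flows from ``config.seed``; identical configs yield
    identical reports.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    params = ForwardModelParams(noise_sd=config.noise_sd)
    report: dict = {"package_version": __version__,
                    "config": asdict(config), "config_hash": config.hash(),
                    "stages": {}}

    # stage 1: lattice session + decoding
    stage_t = time.time()
    lattice = build_hex_lattice(config.lattice_spacing, config.lattice_max_distance)
    responses = generate_lattice_session(
        params, lattice, n_flies=config.n_flies, n_trials=config.n_trials,
        seed=int(rng.integers(2**31)))
    result = cross_validate_decoder(responses, lattice, scheme=config.decoder_scheme)
    tuning = angular_tuning(responses, lattice)
    reg = sincos_regression(tuning.angles, tuning.right_mean - tuning.left_mean,
                            tuning.right_mean + tuning.left_mean)
    report["stages"]["spatial_decoding"] = {
        "n_positions": len(lattice),
        "n_angles": len(lattice.unique_angles),
        "n_trials_decoded": int(len(result.angular_error_deg)),
        "median_angular_error_deg": result.median_angular_error,
        "mean_angular_error_deg": result.mean_angular_error,
        "diff_sin_r2": reg["diff_vs_sin"][2],
        "sum_cos_r2": reg["sum_vs_cos"][2],
        "elapsed_s": round(time.time() - stage_t, 3),
    }
    logger.info("spatial decoding done in %.2fs",
                report["stages"]["spatial_decoding"]["elapsed_s"])

    # stage 2: distance-tuning recovery
    stage_t = time.time()
    from .synthetic import logistic_response
    d = np.repeat(PRINTED_DISTANCES, config.n_flies * config.n_trials)
    fly = np.tile(np.repeat(np.arange(config.n_flies), config.n_trials),
                  len(PRINTED_DISTANCES))
    resp = logistic_response(d, params) + rng.normal(0, config.noise_sd, len(d))
    fit = fit_sigmoid(TuningCurve(distances=d, responses=resp, fly_ids=fly))
    report["stages"]["distance_tuning"] = {
        "true_ed50_mm": params.ed50, "fitted_ed50_mm": fit.ed50,
        "fitted_slope_mm": fit.slope, "rse": fit.rse,
        "converged": fit.converged,
        "elapsed_s": round(time.time() - stage_t, 3),
    }

    # stage 3: toy connectome profile
    stage_t = time.time()
    table = generate_toy_connectome(default_toy_connectome_spec())
    sel = select_downstream_types(table, "DA1_lPN", roi_filter=("LH",))
    import warnings
    with warnings.catch_warnings():
        # the toy connectome plants a glomerulus with missing side labels
        warnings.simplefilter("ignore", UserWarning)
        prof = contra_ipsi_profile(table, "il3LN6")
    da1 = prof[prof.glomerulus == "DA1"].iloc[0]
    report["stages"]["connectome"] = {
        "n_included_types": len(sel.included()),
        "n_excluded_types": len(sel.excluded()),
        "da1_contra_ipsi_ratio": float(da1.contra_ipsi_ratio),
        "elapsed_s": round(time.time() - stage_t, 3),
    }
    report["elapsed_s"] = round(time.time() - t0, 3)
    return report


TABLE_SCHEMAS = {
    "trace": {"columns": ["time_s", "roi", "side", "dff"],
              "numeric": ["time_s", "dff"],
              "monotone_by": (["roi", "side"], "time_s")},
    "responses": {"columns": ["fly_id", "trial", "pos_index", "left", "right"],
                  "numeric": ["left", "right"]},
    "trajectory": {"columns": ["frame", "fly_id", "x_mm", "y_mm",
                               "orientation_deg"],
                   "numeric": ["frame", "x_mm", "y_mm", "orientation_deg"]},
    "treadmill": {"columns": ["frame", "forward", "lateral", "rotational"],
                  "numeric": ["frame", "forward", "lateral", "rotational"],
                  "monotone_by": ([], "frame")},
    "synapse": {"columns": ["pre_type", "post_type", "pre_id", "post_id",
                            "roi", "side", "weight"],
                "numeric": ["weight"]},
}


def validate_tables(path, schema: str) -> dict:
    """Validate a CSV against one of the package's table schemas.

    Returns ``{"ok": bool, "errors": [...]}`` with row/column
    diagnostics for missing columns, non-numeric values, and
    non-monotone time/frame columns.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"one of {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    errors = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file
        return {"ok": False, "errors": [f"unreadable file: {exc}"]}
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return {"ok": False, "errors": errors}
    for col in spec.get("numeric", []):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            errors.append(f"column {col!r}: non-numeric values at rows "
                          f"{list(df.index[bad][:5])}")
    if "monotone_by" in spec:
        group_cols, time_col = spec["monotone_by"]
        groups = df.groupby(group_cols) if group_cols else [((), df)]
        for key, g in groups:
            t = pd.to_numeric(g[time_col], errors="coerce")
            if (t.diff().dropna() <= 0).any():
                errors.append(f"column {time_col!r} not strictly increasing "
                              f"in group {key}")
    if schema == "synapse":
        w = pd.to_numeric(df["weight"], errors="coerce")
        if (w < 1).any():
            errors.append("column 'weight': values below 1")
        bad_side = set(df["side"].unique()) - {"ipsi", "contra", "unknown"}
        if bad_side:
            errors.append(f"column 'side': unknown labels {sorted(bad_side)}")
    return {"ok": not errors, "errors": errors}
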