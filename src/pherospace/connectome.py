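"""Connectome synapse-table and skeleton analyses.

Operates on neuprint-style synapse-count exports (pre_type, post_type,
pre_id, post_id, roi, side, weight) and standard 7-column SWC skeletons:

* downstream-partner selection by absolute count and relative input
  fraction (the 10/50-synapse, 4%/0.5% boundary-line rule);
* input-selectivity classification (multimodal / DA1-selective /
  mixed-olfactory);
* contra/ipsi ORN-input ratios of commissural interneurons per
  glomerulus;
* cable fraction inside a neuropil volume on 1-µm-resampled, pruned
  skeletons;
* a one-sample branch-count test and Ward clustering of a supplied
  morphological-similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

__all__ = [
    "SYNAPSE_COLUMNS",
    "validate_synapse_table",
    "PartnerSelection",
    "InputClassification",
    "SkeletonSample",
    "BoxMask",
    "select_downstream_types",
    "classify_input_selectivity",
    "contra_ipsi_profile",
    "read_swc",
    "resample_skeleton",
    "cable_fraction_in_volume",
    "branch_count_test",
    "ward_cluster",
]

SYNAPSE_COLUMNS = ("pre_type", "post_type", "pre_id", "post_id",
                   "roi", "side", "weight")

# inclusion rule constants: cell types with <= EXCLUDE_MAX seed inputs are
# excluded, >= INCLUDE_MIN included irrespective of fraction; in between the
# boundary line through (10 synapses, 4%) and (50 synapses, 0.5%) applies
EXCLUDE_MAX = 10
INCLUDE_MIN = 51
_LINE_SLOPE = (0.5 - 4.0) / (50.0 - 10.0)  # % per synapse = -0.0875


def inclusion_threshold_pct(n_synapses: float) -> float:
    """Relative-input threshold (%) at a synapse count on the boundary
    line through (10, 4%) and (50, 0.5%)."""
    return 4.0 + _LINE_SLOPE * (n_synapses - 10.0)


def validate_synapse_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SYNAPSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")
    w = table["weight"]
    if (w < 1).any() or not np.allclose(w, w.astype(int)):
        raise ValueError("weights must be positive integers")
    bad = set(table["side"].unique()) - {"ipsi", "contra", "unknown"}
    if bad:
        raise ValueError(f"unknown side labels: {sorted(bad)}")
    return table


@dataclass(frozen=True)
class PartnerSelection:
    """Per-downstream-type selection decisions."""

    seed_type: str
    roi_filter: tuple | None
    table: pd.DataFrame  # post_type, n_synapses, total_inputs, pct, decision, rule

    def included(self) -> list[str]:
        return sorted(self.table.loc[self.table.decision == "include", "post_type"])

    def excluded(self) -> list[str]:
        return sorted(self.table.loc[self.table.decision == "exclude", "post_type"])


@dataclass(frozen=True)
class InputClassification:
    cell_type: str
    olfactory_pn_input: float
    da1_pn_input: float
    sensory_input: float
    label: str  # multimodal | DA1-selective | mixed-olfactory | unclassifiable


def select_downstream_types(table: pd.DataFrame, seed_type: str,
                            roi_filter=None,
                            total_inputs: dict | None = None) -> PartnerSelection:
    """Select downstream cell types of ``seed_type``.

    Rules: not more than 10 seed synapses → exclude; more than 50 →
    include irrespective of the relative input; between 11 and 50 →
    include only when the relative input (%) lies strictly above the
    line through (10 synapses, 4%) and (50 synapses, 0.5%).

    ``roi_filter`` restricts the *seed* connections counted (e.g. the LH
    for lPN seeds); the relative fraction divides by the cell type's
    total inputs across the whole table unless ``total_inputs``
    overrides it.
    """
    validate_synapse_table(table)
    seed = table[table.pre_type == seed_type]
    if roi_filter is not None:
        roi_filter = tuple(np.atleast_1d(roi_filter))
        seed = seed[seed.roi.isin(roi_filter)]
    n_by_type = seed.groupby("post_type")["weight"].sum()
    if total_inputs is None:
        total_inputs = table.groupby("post_type")["weight"].sum().to_dict()
    rows = []
    for post_type, n in n_by_type.items():
        total = total_inputs.get(post_type)
        if total is None or total <= 0:
            raise ValueError(f"no total input count for {post_type!r}")
        pct = 100.0 * n / total
        if n <= EXCLUDE_MAX:
            decision, rule = "exclude", f"<= {EXCLUDE_MAX} inputs"
        elif n >= INCLUDE_MIN:
            decision, rule = "include", f"> {INCLUDE_MIN - 1} inputs"
        else:
            thr = inclusion_threshold_pct(n)
            if pct > thr:
                decision, rule = "include", f"above line ({pct:.3g}% > {thr:.3g}%)"
            else:
                decision, rule = "exclude", f"at/below line ({pct:.3g}% <= {thr:.3g}%)"
        rows.append({"post_type": post_type, "n_synapses": int(n),
                     "total_inputs": int(total), "pct": pct,
                     "decision": decision, "rule": rule})
    return PartnerSelection(seed_type=seed_type, roi_filter=roi_filter,
                            table=pd.DataFrame(rows))


def classify_input_selectivity(table: pd.DataFrame, cell_type: str,
                               pathway_labels: dict) -> InputClassification:
    """Classify a third-order cell type by its input composition.

    ``pathway_labels`` maps pre_type → ("pn", glomerulus) for
    uniglomerular olfactory PNs, ("sensory", pathway) for non-olfactory
    sensory pathways, or ("other", None). Presynaptic partners are
    considered when they provide more than 0.5% of the cell's inputs or
    more than 10 synapses. A cell is *multimodal* when its sensory-
    pathway input exceeds 25% of its uniglomerular-PN olfactory input;
    otherwise *DA1-selective* when DA1 PNs provide more than 50% of the
    olfactory input, else *mixed-olfactory*.
    """
    validate_synapse_table(table)
    inputs = table[table.post_type == cell_type]
    if inputs.empty:
        raise ValueError(f"no inputs to {cell_type!r} in the table")
    total = inputs["weight"].sum()
    by_pre = inputs.groupby("pre_type")["weight"].sum()
    considered = by_pre[(100.0 * by_pre / total > 0.5) | (by_pre > 10)]
    olf = da1 = sens = 0.0
    for pre_type, w in considered.items():
        kind, detail = pathway_labels.get(pre_type, ("other", None))
        if kind == "pn":
            olf += w
            if detail == "DA1":
                da1 += w
        elif kind == "sensory":
            sens += w
    if olf == 0:
        label = "unclassifiable"
    elif sens > 0.25 * olf:
        label = "multimodal"
    elif da1 > 0.5 * olf:
        label = "DA1-selective"
    else:
        label = "mixed-olfactory"
    return InputClassification(cell_type=cell_type, olfactory_pn_input=olf,
                               da1_pn_input=da1, sensory_input=sens, label=label)


def contra_ipsi_profile(table: pd.DataFrame, ln_type: str,
                        orn_prefix: str = "ORN_",
                        pn_types=None) -> pd.DataFrame:
    """Per-glomerulus contralateral/ipsilateral ORN-input ratio of a
    commissural interneuron, with its PN-output fraction.

    Antennal-lobe records carry the glomerulus in the ``roi`` column.
    Glomeruli whose ORN records lack side labels are dropped with a
    warning; a zero ipsilateral count yields a NaN ratio (flagged, not
    infinite). ``pn_types`` is the set of post types counted as
    uniglomerular PNs for the output fraction.
    """
    validate_synapse_table(table)
    orn_in = table[(table.post_type == ln_type)
                   & table.pre_type.str.startswith(orn_prefix)]
    if orn_in.empty:
        raise ValueError(f"no ORN inputs to {ln_type!r}")
    if not (orn_in.side != "unknown").any():
        raise ValueError("no side-labeled ORN records")
    rows = []
    for glom, g in orn_in.groupby("roi"):
        unknown = g.loc[g.side == "unknown", "weight"].sum()
        if unknown > 0:
            warnings.warn(f"glomerulus {glom}: dropping {unknown} synapses "
                          "with missing ORN side information", stacklevel=2)
        ipsi = int(g.loc[g.side == "ipsi", "weight"].sum())
        contra = int(g.loc[g.side == "contra", "weight"].sum())
        if ipsi == 0 and contra == 0:
            continue
        out = table[(table.pre_type == ln_type) & (table.roi == glom)]
        out_total = out["weight"].sum()
        if pn_types is None:
            on_pn = out[out.post_type.str.contains("PN", case=False)]["weight"].sum()
        else:
            on_pn = out[out.post_type.isin(pn_types)]["weight"].sum()
        rows.append({
            "glomerulus": glom,
            "ipsi_orn_input": ipsi,
            "contra_orn_input": contra,
            "contra_ipsi_ratio": contra / ipsi if ipsi > 0 else np.nan,
            "pn_output_fraction": on_pn / out_total if out_total > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# skeletons


@dataclass(frozen=True)
class SkeletonSample:
    """An SWC skeleton with an optional dendrite prune point.

    ``nodes`` has columns (id, x, y, z, parent) in µm; parent −1 marks
    the root. ``prune_node`` selects the subtree kept for dendritic
    analyses; ``step`` is the resampling interval in µm.
    """

    nodes: pd.DataFrame
    prune_node: int | None = None
    step: float = 1.0

    def __post_init__(self):
        need = {"id", "x", "y", "z", "parent"}
        if not need.issubset(self.nodes.columns):
            raise ValueError(f"skeleton nodes need columns {sorted(need)}")
        ids = set(self.nodes["id"])
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        if self.prune_node is not None and self.prune_node not in ids:
            raise ValueError(f"prune node {self.prune_node} not in skeleton")


@dataclass(frozen=True)
class BoxMask:
    """Axis-aligned box volume with an inside test (µm)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    name: str = "box"

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=1)


def read_swc(path) -> SkeletonSample:
    """Read a standard 7-column SWC file (id, type, x, y, z, radius,
    parent)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["id", "type", "x", "y", "z", "radius", "parent"])
    return SkeletonSample(nodes=df[["id", "x", "y", "z", "parent"]].copy())


def _children_map(nodes: pd.DataFrame) -> dict:
    ch: dict = {}
    for nid, parent in zip(nodes["id"], nodes["parent"]):
        if parent != -1:
            ch.setdefault(parent, []).append(nid)
    return ch


def _prune_to_subtree(skel: SkeletonSample) -> pd.DataFrame:
    nodes = skel.nodes
    if skel.prune_node is None:
        return nodes
    ch = _children_map(nodes)
    keep = set()
    stack = [skel.prune_node]
    while stack:
        nid = stack.pop()
        keep.add(nid)
        stack.extend(ch.get(nid, []))
    sub = nodes[nodes["id"].isin(keep)].copy()
    sub.loc[sub["id"] == skel.prune_node, "parent"] = -1
    return sub


def resample_skeleton(skel: SkeletonSample) -> np.ndarray:
    """Evenly spaced sample points along the (pruned) skeleton cable.

    The skeleton is decomposed into unbranched paths between root,
    branch and leaf nodes; each path is resampled at arc-length
    multiples of ``step`` (endpoints included), giving an even node
    distribution along the cable. Returns an (n, 3) array of points.
    """
    nodes = _prune_to_subtree(skel)
    xyz = {nid: np.array([x, y, z]) for nid, x, y, z in
           zip(nodes["id"], nodes["x"], nodes["y"], nodes["z"])}
    ch = _children_map(nodes)
    present = set(nodes["id"])
    roots = [nid for nid, par in zip(nodes["id"], nodes["parent"])
             if par == -1 or par not in present]
    degree_out = {nid: len(ch.get(nid, [])) for nid in present}

    def is_junction(nid):
        return nid in roots or degree_out.get(nid, 0) != 1

    points = []
    for start in present:
        if not is_junction(start):
            continue
        for child in ch.get(start, []):
            # walk the unbranched path from `start` through `child`
            path = [xyz[start], xyz[child]]
            cur = child
            while degree_out.get(cur, 0) == 1:
                cur = ch[cur][0]
                path.append(xyz[cur])
            path = np.array(path)
            seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
            arclen = np.concatenate([[0.0], np.cumsum(seg)])
            L = arclen[-1]
            if L == 0:
                points.append(path[0])
                continue
            s = np.arange(0.0, L, skel.step)
            if L - s[-1] > 1e-9:
                s = np.concatenate([s, [L]])
            resampled = np.column_stack([
                np.interp(s, arclen, path[:, k]) for k in range(3)])
            points.append(resampled)
    if not points:
        raise ValueError("skeleton has no cable to resample")
    pts = np.vstack([np.atleast_2d(p) for p in points])
    return pts


def cable_fraction_in_volume(skel: SkeletonSample, mask) -> float:
    """Fraction of the pruned, 1-µm-resampled skeleton nodes inside the
    volume: inside-nodes divided by all nodes, in [0, 1]."""
    pts = resample_skeleton(skel)
    inside = np.asarray(mask.contains(pts), dtype=bool)
    return float(inside.sum()) / float(len(pts))


# ---------------------------------------------------------------------------
# population statistics on morphology


def branch_count_test(counts, popmean: float = 1.0) -> dict:
    """One-sample t-test of the mean branch count against ``popmean``
    (1 = the usual single connecting neurite)."""
    c = np.asarray(counts, dtype=float)
    if len(c) < 2:
        raise ValueError("need at least two counts")
    mean = float(c.mean())
    sd = float(c.std(ddof=1))
    if sd == 0:
        p = 1.0 if mean == popmean else 0.0
        return {"test": "one-sample t-test", "mean": mean, "sd": 0.0,
                "statistic": float("inf") if mean != popmean else 0.0,
                "p_value": p, "note": "zero variance: exact report"}
    res = _stats.ttest_1samp(c, popmean)
    return {"test": "one-sample t-test", "mean": mean, "sd": sd,
            "statistic": float(res.statistic), "p_value": float(res.pvalue)}


def ward_cluster(similarity: np.ndarray, k: int = 3):
    """Ward hierarchical clustering of a symmetric similarity matrix.

    The similarity is converted to a distance as 1 − s/s_max before
    linkage. Returns (labels, linkage matrix); labels are 1..k and only
    meaningful up to permutation.
    """
    S = np.asarray(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    if k < 1 or k > len(S):
        raise ValueError("k out of range")
    D = 1.0 - S / S.max()
    np.fill_diagonal(D, 0.0)
    Z = _hier.linkage(squareform(D, checks=False), method="ward")
    labels = _hier.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z
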