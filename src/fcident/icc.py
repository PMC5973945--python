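"""Edgewise intraclass correlation (ICC) and functional-network summaries.

For subject identifiability, each edge's connectivity values are grouped by
subject with the sessions as ratings; a high ICC means the edge separates
subjects well (a strong edgewise fingerprint).  For task identifiability the
conditions are the groups and the subjects the ratings.

The default variant is the one-way random-effects ICC(1,1):

    ICC = (MS_between - MS_within) / (MS_between + (k - 1) * MS_within)

with ``k`` ratings per group.  The two-way absolute-agreement ICC(A,1)
(Shrout & Fleiss ICC(2,1)) is available via ``variant="agreement"``.
Negative values are retained (they indicate within-group disagreement
exceeding between-group variance); edges with zero total variance are
returned as NaN and excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fc import CohortStack, devectorize, edge_index_pairs

__all__ = ["ICCMap", "FNSummary", "icc_oneway", "icc_agreement", "edgewise_icc", "fn_summary", "nodal_density"]


def icc_oneway(y: np.ndarray) -> np.ndarray:
    """One-way random-effects ICC(1,1), vectorized over the leading axes.

    ``y`` has shape (..., n_groups, k); returns shape (...,).
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape[-2], y.shape[-1]
    if n < 2 or k < 2:
        raise ValueError("need at least 2 groups and 2 ratings per group")
    gmean = y.mean(axis=(-2, -1), keepdims=True)
    gm = y.mean(axis=-1, keepdims=True)
    ss_between = k * ((gm - gmean) ** 2).sum(axis=(-2, -1))
    ss_within = ((y - gm) ** 2).sum(axis=(-2, -1))
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    denom = msb + (k - 1) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (msb - msw) / denom, np.nan)
    return out


def icc_agreement(y: np.ndarray) -> np.ndarray:
    """Two-way absolute-agreement ICC(A,1) (Shrout-Fleiss ICC(2,1)), vectorized."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape[-2], y.shape[-1]
    if n < 2 or k < 2:
        raise ValueError("need at least 2 groups and 2 ratings per group")
    gmean = y.mean(axis=(-2, -1), keepdims=True)
    row_m = y.mean(axis=-1, keepdims=True)
    col_m = y.mean(axis=-2, keepdims=True)
    msr = k * ((row_m - gmean) ** 2).sum(axis=(-2, -1)) / (n - 1)
    msc = n * ((col_m - gmean) ** 2).sum(axis=(-2, -1)) / (k - 1)
    sse = ((y - row_m - col_m + gmean) ** 2).sum(axis=(-2, -1))
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > 1e-300, (msr - mse) / denom, np.nan)
    return out


@dataclass
class ICCMap:
    """Edgewise ICC values with the design that produced them."""

    values: np.ndarray           # (E,), NaN where undefined
    grouping: str                # "subject" or "task"
    k: int                       # ratings per group
    n_groups: int
    n_regions: int
    region_labels: list[str] | None = None
    network_ids: list[str] | None = None
    variant: str = "oneway"

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index_pairs(self.n_regions)

    def to_matrix(self) -> np.ndarray:
        """Square symmetric ICC matrix (diagonal NaN: ICC undefined there)."""
        m = devectorize(np.nan_to_num(self.values), self.n_regions).values
        nan_mask = np.isnan(self.values)
        if nan_mask.any():
            iu = np.triu_indices(self.n_regions, k=1)
            rows, cols = iu[0][nan_mask], iu[1][nan_mask]
            m[rows, cols] = np.nan
            m[cols, rows] = np.nan
        np.fill_diagonal(m, np.nan)
        return m

    def to_frame(self) -> pd.DataFrame:
        idx = self.edge_index
        labels = self.region_labels or [f"R{i + 1}" for i in range(self.n_regions)]
        return pd.DataFrame(
            {
                "region_i": [labels[i] for i in idx[:, 0]],
                "region_j": [labels[j] for j in idx[:, 1]],
                "icc": self.values,
            }
        )


def edgewise_icc(
    stack: CohortStack,
    grouping: str = "subject",
    variant: str = "oneway",
    task_rating_visit: str | None = None,
) -> ICCMap:
    """Per-edge ICC of a cohort stack.

    grouping="subject": groups are subjects, ratings their sessions (test,
    retest, ...).  grouping="task": groups are conditions, ratings the
    subjects; when a condition has several visits the per-subject average FC
    is used as the rating unless ``task_rating_visit`` names a single visit.
    The design must be balanced.
    """
    fn = {"oneway": icc_oneway, "agreement": icc_agreement}.get(variant)
    if fn is None:
        raise ValueError(f"unknown ICC variant {variant!r}")
    sess = stack.sessions
    x = stack.edge_matrix

    if grouping == "subject":
        subjects = stack.subjects
        counts = sess.groupby("subject").size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced design: subjects have differing session counts")
        k = int(counts.iloc[0])
        cols = [np.flatnonzero((sess["subject"] == s).to_numpy()) for s in subjects]
        y = np.stack([x[:, c] for c in cols], axis=1)  # (E, n_subjects, k)
        n_groups = len(subjects)
    elif grouping == "task":
        conditions = stack.conditions
        subjects = stack.subjects
        if len(conditions) < 2:
            raise ValueError("task grouping needs at least 2 conditions")
        if task_rating_visit is not None:
            sel = stack.select(visit=task_rating_visit)
            sess_sel, x_sel = sel.sessions, sel.edge_matrix
        else:
            sess_sel, x_sel = sess, x
        blocks = []
        for cond in conditions:
            cond_cols = []
            for s in subjects:
                c = np.flatnonzero(
                    ((sess_sel["condition"] == cond) & (sess_sel["subject"] == s)).to_numpy()
                )
                if c.size == 0:
                    raise ValueError(f"unbalanced design: subject {s} missing condition {cond}")
                cond_cols.append(x_sel[:, c].mean(axis=1))
            blocks.append(np.stack(cond_cols, axis=1))
        y = np.stack(blocks, axis=1)  # (E, n_conditions, n_subjects)
        k = len(subjects)
        n_groups = len(conditions)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    values = fn(y)
    return ICCMap(
        values=values,
        grouping=grouping,
        k=k,
        n_groups=n_groups,
        n_regions=stack.n_regions,
        region_labels=stack.region_labels,
        network_ids=stack.network_ids,
        variant=variant,
    )


@dataclass
class FNSummary:
    """Functional-network block summaries of an edgewise ICC map."""

    blocks: pd.DataFrame      # one row per within/between network block
    top5: list[str]
    whole_brain_mean: float


def _block_labels(networks: list[str], idx: np.ndarray) -> np.ndarray:
    ni = np.asarray(networks)
    a, b = ni[idx[:, 0]], ni[idx[:, 1]]
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    return np.where(a == b, a, np.char.add(np.char.add(lo, "-"), hi))


def fn_summary(icc: ICCMap, network_ids: list[str] | None = None) -> FNSummary:
    """Distribution of edgewise ICC per within- and between-network block.

    Blocks are the 8 within-network and 28 between-network region-pair
    groups; the top-5 ranking is by block mean ICC (ties resolved by
    canonical block-label order).  NaN edges are excluded.
    """
    networks = network_ids if network_ids is not None else icc.network_ids
    if networks is None:
        raise ValueError("no network partition available")
    if len(networks) != icc.n_regions:
        raise ValueError("partition does not cover all regions")
    labels = _block_labels(list(map(str, networks)), icc.edge_index)
    df = pd.DataFrame({"block": labels, "icc": icc.values})
    finite = df.dropna(subset=["icc"])
    agg = (
        finite.groupby("block")["icc"]
        .agg(["count", "mean", "std", "min", "median", "max"])
        .reset_index()
        .rename(columns={"count": "n_edges"})
    )
    # stable sort: mean descending, block label ascending on ties
    agg = agg.sort_values(["mean", "block"], ascending=[False, True], kind="mergesort")
    agg = agg.reset_index(drop=True)
    n_total = pd.Series(labels).value_counts()
    agg["n_edges_total"] = agg["block"].map(n_total)
    return FNSummary(
        blocks=agg,
        top5=list(agg["block"].head(5)),
        whole_brain_mean=float(finite["icc"].mean()),
    )


def nodal_density(icc: ICCMap, percentile: float = 95.0) -> np.ndarray:
    """Per-region fraction of incident edges above an ICC percentile threshold.

    threshold = given percentile of the (finite) edgewise ICC distribution;
    density_r = (# suprathreshold edges incident to r) / (n_regions - 1).
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    finite = icc.values[np.isfinite(icc.values)]
    if finite.size == 0:
        raise ValueError("no finite ICC values")
    thr = np.percentile(finite, percentile)
    supra = icc.values > thr
    idx = icc.edge_index
    counts = np.zeros(icc.n_regions)
    np.add.at(counts, idx[supra, 0], 1)
    np.add.at(counts, idx[supra, 1], 1)
    return counts / (icc.n_regions - 1)
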