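"""FC-behavior associations: robustness filtering and predictive modeling.

Two analyses live here.

*Association robustness*: per-edge Pearson correlation between connectivity
and a behavioral score across subjects, filtered to significant edges
(p < alpha) forming the giant component (as in network-based statistics),
intersected between test and retest, and benchmarked against a
score-shuffling permutation null.

*Connectome-based predictive modeling (CPM)*: within each leave-one-out
fold, edges positively and significantly correlated with behavior are ranked
by r x ICC, the top-k edge values are summed into a per-subject strength,
and a univariate linear model predicts the held-out subject's score.
Weighting the ranking by the edgewise ICC favours edges with a strong
individual fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import LeaveOneOut

from .fc import CohortStack, edge_index_pairs

__all__ = [
    "AssociationGraph",
    "RobustnessResult",
    "CPMResult",
    "CPMRegressor",
    "association_matrix",
    "significant_giant_component",
    "robust_intersection",
    "permutation_null",
    "cpm_loocv",
]


def _pearson_edges(x: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson r and two-sided p of x (E x n) against scores (n,)."""
    n = scores.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if scores.std() == 0:
        raise ValueError("behavioral score is constant")
    xs = x - x.mean(axis=1, keepdims=True)
    xsd = xs.std(axis=1)
    zs = (scores - scores.mean()) / scores.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs @ zs) / (n * xsd)
    r = np.clip(np.where(xsd > 0, r, 0.0), -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return r, p


@dataclass
class AssociationGraph:
    """Edgewise FC-behavior correlations, optionally filtered to a subgraph."""

    r: np.ndarray
    p: np.ndarray
    n_regions: int
    kept: np.ndarray                 # boolean mask over edges
    region_labels: list[str] | None = None
    provenance: dict | None = None

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index_pairs(self.n_regions)

    @property
    def n_edges_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def nodes_kept(self) -> np.ndarray:
        idx = self.edge_index[self.kept]
        return np.unique(idx)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        labels = self.region_labels or [f"R{i + 1}" for i in range(self.n_regions)]
        idx = self.edge_index
        for e in np.flatnonzero(self.kept):
            i, j = idx[e]
            g.add_edge(labels[i], labels[j], r=float(self.r[e]), p=float(self.p[e]))
        return g


def association_matrix(
    stack_one_visit: CohortStack, scores: pd.Series | np.ndarray
) -> AssociationGraph:
    """Edgewise Pearson association of connectivity with a behavioral score.

    ``stack_one_visit`` must hold one session per subject.  ``scores`` may be
    a Series indexed by subject id (aligned automatically) or an array in the
    stack's column order.
    """
    sess = stack_one_visit.sessions
    if sess["subject"].duplicated().any():
        raise ValueError("stack must hold one session per subject")
    if isinstance(scores, pd.Series):
        missing = [s for s in sess["subject"] if s not in scores.index]
        if missing:
            raise ValueError(f"scores missing for subjects: {missing}")
        y = scores.loc[sess["subject"]].to_numpy(dtype=float)
    else:
        y = np.asarray(scores, dtype=float)
        if y.size != stack_one_visit.n_sessions:
            raise ValueError("scores length does not match number of subjects")
    r, p = _pearson_edges(stack_one_visit.edge_matrix, y)
    return AssociationGraph(
        r=r,
        p=p,
        n_regions=stack_one_visit.n_regions,
        kept=np.ones(r.size, dtype=bool),
        region_labels=stack_one_visit.region_labels,
        provenance={"n_subjects": int(y.size)},
    )


def _giant_component_mask(edge_mask: np.ndarray, edge_index: np.ndarray, n_regions: int) -> np.ndarray:
    """Keep only edges in the connected component(s) with the most nodes.

    Ties on the maximum node count keep the union of tied components.
    """
    if not edge_mask.any():
        return edge_mask
    idx = edge_index[edge_mask]
    adj = sparse.coo_matrix(
        (np.ones(len(idx)), (idx[:, 0], idx[:, 1])), shape=(n_regions, n_regions)
    )
    n_comp, labels = connected_components(adj, directed=False)
    involved = np.zeros(n_regions, dtype=bool)
    involved[idx[:, 0]] = True
    involved[idx[:, 1]] = True
    sizes = np.bincount(labels[involved], minlength=n_comp)
    best = sizes.max()
    keep_comp = np.flatnonzero(sizes == best)
    node_ok = np.isin(labels, keep_comp) & involved
    out = edge_mask.copy()
    sub = node_ok[idx[:, 0]] & node_ok[idx[:, 1]]
    out[np.flatnonzero(edge_mask)] = sub
    return out


def significant_giant_component(assoc: AssociationGraph, alpha: float = 0.01) -> AssociationGraph:
    """Filter to p < alpha edges, then to the giant connected component."""
    sig = assoc.kept & (assoc.p < alpha)
    kept = _giant_component_mask(sig, assoc.edge_index, assoc.n_regions)
    prov = dict(assoc.provenance or {})
    prov["alpha"] = alpha
    return replace(assoc, kept=kept, provenance=prov)


def robust_intersection(g_test: AssociationGraph, g_retest: AssociationGraph) -> tuple[int, int]:
    """(n_edges, n_nodes) of the test/retest edge-set intersection."""
    if g_test.n_regions != g_retest.n_regions:
        raise ValueError("graphs defined over different region sets")
    both = g_test.kept & g_retest.kept
    idx = g_test.edge_index[both]
    n_nodes = int(np.unique(idx).size) if idx.size else 0
    return int(both.sum()), n_nodes


@dataclass
class RobustnessResult:
    """Observed intersection counts and their permutation-null percentiles."""

    n_edges_intersect: int
    n_nodes_intersect: int
    percentile_edges: float
    percentile_nodes: float
    n_perm: int
    null_edges: np.ndarray
    null_nodes: np.ndarray
    alpha: float


def _critical_r(alpha: float, n: int) -> float:
    """|r| threshold equivalent to a two-sided p < alpha at sample size n."""
    t_crit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    xs = x - x.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, keepdims=True)
    return np.divide(xs, sd, out=np.zeros_like(xs), where=sd > 0)


def _intersection_counts(
    x_test: np.ndarray,
    x_retest: np.ndarray,
    y: np.ndarray,
    alpha: float,
    edge_index: np.ndarray,
    n_regions: int,
) -> tuple[int, int]:
    masks = []
    for x in (x_test, x_retest):
        _, p = _pearson_edges(x, y)
        masks.append(_giant_component_mask(p < alpha, edge_index, n_regions))
    both = masks[0] & masks[1]
    idx = edge_index[both]
    return int(both.sum()), int(np.unique(idx).size) if idx.size else 0


def permutation_null(
    test_stack: CohortStack,
    retest_stack: CohortStack,
    scores: pd.Series | np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> RobustnessResult:
    """Significance of the robust intersection via score shuffling.

    Each permutation applies one shuffle of the behavioral scores to both
    visits and reruns the full filter pipeline.  Percentile = fraction of
    null values strictly below the observed count, x100.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sess = test_stack.sessions
    if isinstance(scores, pd.Series):
        y = scores.loc[sess["subject"]].to_numpy(dtype=float)
    else:
        y = np.asarray(scores, dtype=float)
    retest = retest_stack
    if list(retest.sessions["subject"]) != list(sess["subject"]):
        order = {s: k for k, s in enumerate(retest.sessions["subject"])}
        cols = np.array([order[s] for s in sess["subject"]])
        retest = retest.with_matrix(retest.edge_matrix[:, cols])
    edge_index = test_stack.edge_index
    n_regions = test_stack.n_regions
    obs_e, obs_n = _intersection_counts(
        test_stack.edge_matrix, retest.edge_matrix, y, alpha, edge_index, n_regions
    )
    rng = np.random.default_rng(seed)
    n = y.size
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    perms_z = (perms - perms.mean(axis=0)) / perms.std(axis=0)
    r_crit = _critical_r(alpha, n)
    null_e = np.empty(n_perm, dtype=int)
    null_n = np.empty(n_perm, dtype=int)
    # one matmul per visit yields every permutation's edgewise correlations
    sig = []
    for x in (test_stack.edge_matrix, retest.edge_matrix):
        r_all = _standardize_rows(x) @ perms_z / n  # (E, n_perm)
        sig.append(np.abs(r_all) > r_crit)
    for b in range(n_perm):
        masks = [
            _giant_component_mask(s[:, b], edge_index, n_regions) for s in sig
        ]
        both = masks[0] & masks[1]
        idx = edge_index[both]
        null_e[b] = int(both.sum())
        null_n[b] = int(np.unique(idx).size) if idx.size else 0
    return RobustnessResult(
        n_edges_intersect=obs_e,
        n_nodes_intersect=obs_n,
        percentile_edges=100.0 * float(np.mean(null_e < obs_e)),
        percentile_nodes=100.0 * float(np.mean(null_n < obs_n)),
        n_perm=n_perm,
        null_edges=null_e,
        null_nodes=null_n,
        alpha=alpha,
    )


class CPMRegressor(BaseEstimator, RegressorMixin):
    """Connectome-based predictive model with ICC-weighted edge ranking.

    Parameters
    ----------
    k : number of top-ranked edges summed into the strength score.
    alpha : per-edge significance threshold for the candidate pool
        (positive-r edges with p < alpha).
    icc : optional per-edge ICC used to weight the ranking (r x max(ICC, 0));
        without it edges rank by r alone.

    ``fit`` takes X of shape (n_subjects, n_edges) and the behavioral score
    y; ``predict`` maps held-out connectomes to predicted scores via the
    fitted strength -> score line.
    """

    def __init__(self, k: int = 5, alpha: float = 0.01, icc: np.ndarray | None = None):
        self.k = k
        self.alpha = alpha
        self.icc = icc

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        r, p = _pearson_edges(X.T, y)
        pool = np.flatnonzero((r > 0) & (p < self.alpha))
        if pool.size == 0:
            raise ValueError("empty edge pool: no significant positively correlated edges")
        weight = r[pool]
        if self.icc is not None:
            weight = weight * np.maximum(np.asarray(self.icc, dtype=float)[pool], 0.0)
        order = np.argsort(-weight, kind="stable")
        self.edges_ = pool[order[: self.k]]
        s = X[:, self.edges_].sum(axis=1)
        self.slope_, self.intercept_ = np.polyfit(s, y, 1)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        s = X[:, self.edges_].sum(axis=1)
        return self.intercept_ + self.slope_ * s


@dataclass
class CPMResult:
    """LOOCV predictability over a grid of edge counts."""

    k_grid: list[int]
    r_pred: np.ndarray           # NaN where a fold had an empty pool
    predictions: np.ndarray      # (len(k_grid), n_subjects)
    edges_full: dict             # k -> edges selected on the full sample

    def best(self) -> tuple[int, float]:
        finite = np.where(np.isfinite(self.r_pred), self.r_pred, -np.inf)
        b = int(np.argmax(finite))
        return self.k_grid[b], float(self.r_pred[b])


def cpm_loocv(
    stack: CohortStack,
    scores: pd.Series | np.ndarray,
    icc_values: np.ndarray | None = None,
    k_grid: list[int] | None = None,
    alpha: float = 0.01,
    rank_on_full: bool = False,
) -> CPMResult:
    """Leave-one-out CPM predictability curve over top-k edge counts.

    Edge selection and ranking are recomputed inside every training fold
    (leakage-free); ``rank_on_full=True`` instead fixes selection on the full
    sample.  ``stack`` must hold one session (e.g. the test-retest average)
    per subject.
    """
    sess = stack.sessions
    if sess["subject"].duplicated().any():
        raise ValueError("stack must hold one session per subject")
    if isinstance(scores, pd.Series):
        y = scores.loc[sess["subject"]].to_numpy(dtype=float)
    else:
        y = np.asarray(scores, dtype=float)
    X = stack.edge_matrix.T  # subjects x edges
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for LOOCV")
    if k_grid is None:
        k_grid = list(range(5, 105, 5))

    preds = np.full((len(k_grid), n), np.nan)
    kmax = max(k_grid)
    model = CPMRegressor(k=kmax, alpha=alpha, icc=icc_values)
    if rank_on_full:
        model.fit(X, y)
        full_rank = model.edges_
    for train, test in LeaveOneOut().split(X):
        try:
            if rank_on_full:
                ranked = full_rank
            else:
                model.fit(X[train], y[train])
                ranked = model.edges_
        except ValueError:
            continue  # empty pool in this fold: all k undefined here
        for ki, k in enumerate(k_grid):
            edges = ranked[:k]
            if edges.size == 0:
                continue
            s_train = X[np.ix_(train, edges)].sum(axis=1)
            slope, intercept = np.polyfit(s_train, y[train], 1)
            preds[ki, test] = intercept + slope * X[np.ix_(test, edges)].sum(axis=1)

    r_pred = np.full(len(k_grid), np.nan)
    for ki in range(len(k_grid)):
        ok = np.isfinite(preds[ki])
        if ok.sum() >= 3 and np.std(preds[ki, ok]) > 0:
            r_pred[ki] = np.corrcoef(preds[ki, ok], y[ok])[0, 1]

    model_full = CPMRegressor(k=kmax, alpha=alpha, icc=icc_values)
    try:
        model_full.fit(X, y)
        edges_full = {k: model_full.edges_[:k].copy() for k in k_grid}
    except ValueError:
        edges_full = {}
    return CPMResult(k_grid=list(k_grid), r_pred=r_pred, predictions=preds, edges_full=edges_full)
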