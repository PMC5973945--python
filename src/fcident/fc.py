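"""Functional connectomes: containers, vectorization, and cohort stacking.

A functional connectome (FC) is the square symmetric matrix of Pearson
correlations between regional BOLD time courses.  Cohort-level analyses work
on the *stack*: the strict upper triangle of every session's FC vectorized
into a column of an edges x sessions matrix.

Canonical edge order is row-major over the strict upper triangle
(``(0,1), (0,2), ..., (0,n-1), (1,2), ...``), 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FCMatrix",
    "TimeSeries",
    "CohortStack",
    "SessionTimeSeries",
    "edge_index_pairs",
    "timeseries_to_fc",
    "vectorize_fc",
    "devectorize",
    "split_halves",
    "truncate_frames",
    "stack_cohort",
]

SYMMETRY_TOL = 1e-8

#: canonical networks: 7 Yeo cortical resting-state networks + subcortex
NETWORKS = ("VIS", "SM", "DA", "VA", "L", "FP", "DMN", "SUBC")

# visits sort test before retest; anything else lexicographic
_VISIT_PRIORITY = {"test": 0, "retest": 1}


def _visit_key(v: str) -> tuple:
    return (_VISIT_PRIORITY.get(v, 2), str(v))


def edge_index_pairs(n_regions: int) -> np.ndarray:
    """Return the (E, 2) array of region index pairs (i < j) in canonical order."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


@dataclass
class FCMatrix:
    """Square symmetric signed functional-connectivity matrix.

    Off-diagonal entries are Pearson correlations in [-1, 1]; the diagonal is
    fixed at 1.  ``network_ids`` optionally assigns each region to one of the
    eight canonical functional networks.
    """

    values: np.ndarray
    region_labels: list[str] | None = None
    network_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("FC matrix must be square")
        if n < 3:
            raise ValueError("FC matrix needs at least 3 regions")
        asym = np.max(np.abs(self.values - self.values.T))
        if asym > SYMMETRY_TOL:
            raise ValueError(f"FC matrix asymmetric beyond tolerance ({asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 1.0)
        if self.region_labels is None:
            self.region_labels = [f"R{i + 1}" for i in range(n)]
        if len(self.region_labels) != n:
            raise ValueError("region_labels length mismatch")
        if self.network_ids is not None and len(self.network_ids) != n:
            raise ValueError("network_ids length mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class TimeSeries:
    """Parcellated regional time series, regions x frames."""

    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be 2-D (regions x frames)")
        if self.values.shape[1] < 3:
            raise ValueError("time series needs at least 3 frames")
        if self.region_labels is None:
            self.region_labels = [f"R{i + 1}" for i in range(self.values.shape[0])]
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("region_labels length mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SessionTimeSeries:
    """One session's time series with its cohort metadata."""

    subject: str
    visit: str
    ts: TimeSeries
    condition: str = "rest"


@dataclass
class CohortStack:
    """Edges x sessions matrix of vectorized FCs with per-session metadata.

    ``sessions`` is a DataFrame with columns ``subject``, ``visit``,
    ``condition``; row k describes column k of ``edge_matrix``.
    """

    edge_matrix: np.ndarray
    sessions: pd.DataFrame
    n_regions: int
    region_labels: list[str] | None = None
    network_ids: list[str] | None = None

    def __post_init__(self):
        self.edge_matrix = np.asarray(self.edge_matrix, dtype=float)
        expected_e = self.n_regions * (self.n_regions - 1) // 2
        if self.edge_matrix.shape[0] != expected_e:
            raise ValueError(
                f"edge_matrix has {self.edge_matrix.shape[0]} rows; "
                f"expected {expected_e} for {self.n_regions} regions"
            )
        if self.edge_matrix.shape[1] != len(self.sessions):
            raise ValueError("session metadata does not match number of columns")
        self.sessions = self.sessions.reset_index(drop=True)
        if self.region_labels is None:
            self.region_labels = [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def n_edges(self) -> int:
        return self.edge_matrix.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.edge_matrix.shape[1]

    @property
    def subjects(self) -> list:
        return sorted(self.sessions["subject"].unique())

    @property
    def visits(self) -> list:
        return sorted(self.sessions["visit"].unique(), key=_visit_key)

    @property
    def conditions(self) -> list:
        return sorted(self.sessions["condition"].unique())

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index_pairs(self.n_regions)

    def select(self, visit=None, condition=None, subjects=None) -> "CohortStack":
        """Sub-stack restricted to a visit, a condition and/or a subject list."""
        mask = np.ones(len(self.sessions), dtype=bool)
        if visit is not None:
            mask &= (self.sessions["visit"] == visit).to_numpy()
        if condition is not None:
            mask &= (self.sessions["condition"] == condition).to_numpy()
        if subjects is not None:
            mask &= self.sessions["subject"].isin(list(subjects)).to_numpy()
        return replace(
            self,
            edge_matrix=self.edge_matrix[:, mask],
            sessions=self.sessions.loc[mask].reset_index(drop=True),
        )

    def with_matrix(self, edge_matrix: np.ndarray) -> "CohortStack":
        """Copy of the stack with a new edge matrix and identical metadata."""
        return replace(self, edge_matrix=np.asarray(edge_matrix, dtype=float))

    def column_fc(self, k: int) -> FCMatrix:
        """Devectorize column ``k`` back into a square FC matrix."""
        return devectorize(
            self.edge_matrix[:, k],
            self.n_regions,
            region_labels=self.region_labels,
            network_ids=self.network_ids,
        )


def timeseries_to_fc(
    ts: TimeSeries,
    zscore: bool = True,
    outlier_sd: float | None = None,
) -> FCMatrix:
    """Pearson-correlation FC from regional time courses.

    Parameters
    ----------
    ts : TimeSeries
    zscore : standardize each regional time course first.  Pearson r is
        invariant to this; the flag mirrors common preprocessing.
    outlier_sd : if set, frames where a region deviates more than this many
        SDs from its mean are excluded from every correlation involving that
        region (pairwise-complete).
    """
    x = np.asarray(ts.values, dtype=float)
    n, t = x.shape
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(ts.region_labels[i] for i in bad)
        raise ValueError(f"constant time course: correlation undefined for region(s) {names}")
    if zscore:
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    if outlier_sd is None:
        r = np.corrcoef(x)
    else:
        mu = x.mean(axis=1, keepdims=True)
        s = x.std(axis=1, keepdims=True)
        valid = (np.abs(x - mu) <= outlier_sd * s).astype(float)
        xm = x * valid
        n_ij = valid @ valid.T
        if np.any(n_ij < 3):
            raise ValueError("outlier exclusion leaves fewer than 3 shared frames for some pair")
        sx = xm @ valid.T        # sum of x_i over frames valid for both i and j
        sxx = (x * xm) @ valid.T  # sum of x_i^2 over shared frames
        sxy = xm @ xm.T
        cov = n_ij * sxy - sx * sx.T
        var = n_ij * sxx - sx**2
        denom = np.sqrt(var * var.T)
        if np.any(denom <= 0):
            raise ValueError("zero variance on shared frames after outlier exclusion")
        r = cov / denom
    r = np.clip(r, -1.0, 1.0)
    return FCMatrix(r, region_labels=list(ts.region_labels))


def vectorize_fc(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Strict-upper-triangle edge vector of an FC matrix (canonical order)."""
    if isinstance(fc, FCMatrix):
        m = fc.values
    else:
        m = np.asarray(fc, dtype=float)
        asym = np.max(np.abs(m - m.T))
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(
    v: np.ndarray,
    n_regions: int,
    region_labels: list[str] | None = None,
    network_ids: list[str] | None = None,
) -> FCMatrix:
    """Square symmetric FC (unit diagonal) from a canonical edge vector."""
    v = np.asarray(v, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"edge vector length {v.shape} does not match n={n_regions} (expected {expected})")
    m = np.eye(n_regions)
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    # round-trip overflow beyond [-1,1] by less than 1e-12 is clipped silently
    over = np.abs(m) - 1.0
    m[(over > 0) & (over <= 1e-12)] = np.sign(m[(over > 0) & (over <= 1e-12)])
    return FCMatrix(m, region_labels=region_labels, network_ids=network_ids)


def split_halves(ts: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Split a session's frames into two halves (extra frame goes to the second)."""
    t = ts.n_frames
    if t < 6:
        raise ValueError("need at least 6 frames to split into valid halves")
    h = t // 2
    return (
        TimeSeries(ts.values[:, :h], region_labels=list(ts.region_labels)),
        TimeSeries(ts.values[:, h:], region_labels=list(ts.region_labels)),
    )


def truncate_frames(ts: TimeSeries, n_frames: int) -> TimeSeries:
    """Keep only the first ``n_frames`` frames of a session."""
    if n_frames > ts.n_frames:
        raise ValueError(f"cannot keep {n_frames} frames; session has {ts.n_frames}")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    return TimeSeries(ts.values[:, :n_frames], region_labels=list(ts.region_labels))


def stack_cohort(
    manifest: pd.DataFrame,
    matrices: Mapping[str, FCMatrix] | Sequence[FCMatrix],
    network_ids: list[str] | None = None,
) -> CohortStack:
    """Vectorize and stack a cohort of FC matrices into a CohortStack.

    ``manifest`` needs columns ``subject``, ``visit`` and optionally
    ``condition`` and ``path``; ``matrices`` maps the manifest's ``path``
    entries (or positional row order, if a sequence) to FCMatrix objects.
    Columns are ordered deterministically by (subject, condition, visit)
    regardless of manifest order.
    """
    manifest = manifest.copy().reset_index(drop=True)
    if "condition" not in manifest.columns:
        manifest["condition"] = "rest"
    required = {"subject", "visit", "condition"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    if isinstance(matrices, Mapping):
        fcs = [matrices[p] for p in manifest["path"]]
    else:
        fcs = list(matrices)
        if len(fcs) != len(manifest):
            raise ValueError("number of matrices does not match manifest rows")

    labels = fcs[0].region_labels
    n = fcs[0].n_regions
    for fc in fcs[1:]:
        if fc.n_regions != n or fc.region_labels != labels:
            raise ValueError("all FC matrices must share size and region order")

    # balanced design: every subject x condition must have every visit
    visits = sorted(manifest["visit"].unique(), key=_visit_key)
    missing = []
    for (subj, cond), grp in manifest.groupby(["subject", "condition"]):
        if sorted(grp["visit"].unique(), key=_visit_key) != visits:
            missing.append(str(subj))
    if missing:
        raise ValueError(f"missing visits for subjects: {', '.join(sorted(set(missing)))}")

    order = sorted(
        range(len(manifest)),
        key=lambda k: (
            str(manifest["subject"][k]),
            str(manifest["condition"][k]),
            _visit_key(str(manifest["visit"][k])),
        ),
    )
    edge_matrix = np.column_stack([vectorize_fc(fcs[k]) for k in order])
    sessions = manifest.iloc[order][["subject", "visit", "condition"]].reset_index(drop=True)
    return CohortStack(
        edge_matrix=edge_matrix,
        sessions=sessions,
        n_regions=n,
        region_labels=list(labels),
        network_ids=network_ids if network_ids is not None else fcs[0].network_ids,
    )
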