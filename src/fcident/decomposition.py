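"""Group-level PCA of the cohort stack and I_diff-optimal reconstruction.

The edges x sessions stack is centered **per session** (each column's mean
over edges, mu_k, is subtracted; it is added back on reconstruction).  This
is deliberately the opposite of the per-feature centering most PCA libraries
apply when samples are sessions: here the sessions are the variables and the
edges the observations, so an economy SVD of the column-centered matrix
yields orthonormal edge-space eigenvectors ("connectivity modes") ranked by
explained variance.

Reconstruction at m components keeps the m highest-variance modes:
high-variance modes carry cohort-level structure, intermediate ones the
subject fingerprint, and the tail mostly session noise.  Sweeping m and
scoring each reconstruction with the differential identifiability I_diff
locates the optimum m* = argmax_m I_diff(m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fc import CohortStack, SessionTimeSeries, stack_cohort, timeseries_to_fc, truncate_frames
from .identifiability import identifiability_from_stack

__all__ = [
    "ConnectomePCA",
    "SweepResult",
    "decompose",
    "reconstruct",
    "project_new",
    "default_m_grid",
    "sweep_components",
    "bootstrap_sweep",
    "frame_length_sweep",
]


class ConnectomePCA(BaseEstimator):
    """PCA over vectorized connectomes with per-session centering.

    Follows the scikit-learn estimator protocol: ``fit`` takes the
    edges x sessions matrix (or a :class:`~fcident.fc.CohortStack`).

    Attributes (after fit)
    ----------------------
    modes_ : (E, M) orthonormal edge-space eigenvectors, variance-ranked.
    scores_ : (M, S) mode weights per session; centered data = modes_ @ scores_.
    column_means_ : (S,) per-session mean over edges (mu_k).
    explained_variance_ratio_ : (M,) fraction of centered variance per mode.
    n_components_ : M (= min(E, S) economy rank).
    """

    def __init__(self, sign_convention: bool = True):
        self.sign_convention = sign_convention

    def fit(self, X, y=None):
        X = self._as_matrix(X)
        e, s = X.shape
        if s < 2:
            raise ValueError("need at least 2 sessions")
        if e < s:
            raise ValueError("need at least as many edges as sessions")
        self.column_means_ = X.mean(axis=0)
        xc = X - self.column_means_
        if not np.any(xc):
            raise ValueError("stack has zero variance after centering")
        u, sv, vt = np.linalg.svd(xc, full_matrices=False)
        if self.sign_convention:
            # fix the arbitrary eigenvector sign: largest-|.| element positive
            flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(u.shape[1])])
            flip[flip == 0] = 1.0
            u = u * flip
            vt = vt * flip[:, None]
        self.modes_ = u
        self.scores_ = sv[:, None] * vt
        var = sv**2
        self.explained_variance_ratio_ = var / var.sum()
        self.n_components_ = u.shape[1]
        self.n_edges_ = e
        self.n_sessions_ = s
        return self

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, CohortStack):
            X = X.edge_matrix
        return np.asarray(X, dtype=float)

    def _check_fitted(self):
        if not hasattr(self, "modes_"):
            raise ValueError("estimator is not fitted")

    def reconstruct(self, m: int | None = None) -> np.ndarray:
        """Training-stack reconstruction from the first ``m`` modes (+ mu_k)."""
        self._check_fitted()
        if m is None:
            m = self.n_components_
        if not 0 <= m <= self.n_components_:
            raise ValueError(f"m={m} outside [0, {self.n_components_}]")
        return self.modes_[:, :m] @ self.scores_[:m] + self.column_means_

    def transform(self, X) -> np.ndarray:
        """Mode weights of new sessions (columns centered by their own mean)."""
        self._check_fitted()
        X = self._as_matrix(X)
        if X.shape[0] != self.n_edges_:
            raise ValueError(f"edge count mismatch: got {X.shape[0]}, fitted on {self.n_edges_}")
        return self.modes_.T @ (X - X.mean(axis=0))

    def project(self, X, m: int | None = None) -> np.ndarray:
        """Reconstruct new sessions through the first ``m`` training modes.

        Each new column is centered by its own mean, projected onto the
        training basis, reconstructed, and its mean added back.
        """
        self._check_fitted()
        X = self._as_matrix(X)
        if X.shape[0] != self.n_edges_:
            raise ValueError(f"edge count mismatch: got {X.shape[0]}, fitted on {self.n_edges_}")
        if m is None:
            m = self.n_components_
        if not 0 <= m <= self.n_components_:
            raise ValueError(f"m={m} outside [0, {self.n_components_}]")
        mu = X.mean(axis=0)
        xc = X - mu
        basis = self.modes_[:, :m]
        return basis @ (basis.T @ xc) + mu


def decompose(stack: CohortStack) -> ConnectomePCA:
    """Fit the group-level PCA basis on a cohort stack."""
    return ConnectomePCA().fit(stack)


def reconstruct(basis: ConnectomePCA, stack: CohortStack, m: int | None = None) -> CohortStack:
    """Stack reconstructed at ``m`` components, metadata preserved."""
    return stack.with_matrix(basis.reconstruct(m))


def project_new(basis: ConnectomePCA, new_stack: CohortStack, m: int | None = None) -> CohortStack:
    """Reconstruct held-out sessions through a training basis."""
    return new_stack.with_matrix(basis.project(new_stack.edge_matrix, m))


def default_m_grid(n_sessions: int, cap: int = 160) -> list[int]:
    """The standard component grid {2, 5, 10, 20, ..., 160}, clipped to S."""
    hi = min(cap, n_sessions)
    grid = [m for m in (2, 5) if m <= hi]
    grid += list(range(10, hi + 1, 10))
    return grid


@dataclass
class SweepResult:
    """I_diff as a function of the number of retained components."""

    m_grid: list[int]
    idiff_orig: float
    idiff_recon: np.ndarray
    r2_kept: np.ndarray
    m_star: int
    idiff_star: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.m_grid,
                "idiff_orig": self.idiff_orig,
                "idiff_recon": self.idiff_recon,
                "r2_kept": self.r2_kept,
            }
        )


def _default_scorer(stack: CohortStack) -> float:
    return identifiability_from_stack(stack).I_diff


def sweep_components(
    stack: CohortStack,
    m_grid: Sequence[int] | None = None,
    scorer: Callable[[CohortStack], float] | None = None,
    basis: ConnectomePCA | None = None,
) -> SweepResult:
    """Score reconstructions over a component grid and locate m*.

    ``scorer`` maps a (reconstructed) stack to an identifiability score;
    default is I_diff between the stack's two visits.  Ties in the argmax
    resolve to the smallest m.
    """
    if scorer is None:
        scorer = _default_scorer
    if basis is None:
        basis = decompose(stack)
    if m_grid is None:
        m_grid = default_m_grid(basis.n_components_)
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("empty m grid")
    if any(m < 0 or m > basis.n_components_ for m in m_grid):
        raise ValueError(f"m grid must lie within [0, {basis.n_components_}]")
    idiff_orig = scorer(stack)
    cum = np.concatenate([[0.0], np.cumsum(basis.explained_variance_ratio_)])
    idiff_recon = np.array([scorer(reconstruct(basis, stack, m)) for m in m_grid])
    r2_kept = np.array([cum[m] for m in m_grid])
    star = int(np.argmax(idiff_recon))  # np.argmax returns the first (smallest m) maximum
    return SweepResult(
        m_grid=m_grid,
        idiff_orig=float(idiff_orig),
        idiff_recon=idiff_recon,
        r2_kept=r2_kept,
        m_star=m_grid[star],
        idiff_star=float(idiff_recon[star]),
    )


def bootstrap_sweep(
    stack: CohortStack,
    n_boot: int = 100,
    subset_subjects: int | None = None,
    m_grid: Sequence[int] | None = None,
    scorer: Callable[[CohortStack], float] | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Subject-level bootstrap of the component sweep.

    Each resample draws ``subset_subjects`` subjects without replacement
    (all their sessions travel together), refits the basis and reruns the
    sweep.  Returns per-m mean and SD of the reconstructed I_diff plus the
    mean original I_diff.
    """
    subjects = stack.subjects
    if subset_subjects is None:
        subset_subjects = len(subjects)
    if subset_subjects > len(subjects):
        raise ValueError("subset_subjects exceeds cohort size")
    rng = np.random.default_rng(seed)
    if m_grid is None:
        n_sess_sub = subset_subjects * (stack.n_sessions // len(subjects))
        m_grid = default_m_grid(min(n_sess_sub, stack.n_edges))
    curves, origs, stars = [], [], []
    for _ in range(n_boot):
        chosen = rng.choice(len(subjects), size=subset_subjects, replace=False)
        sub = stack.select(subjects=[subjects[i] for i in chosen])
        res = sweep_components(sub, m_grid=m_grid, scorer=scorer)
        curves.append(res.idiff_recon)
        origs.append(res.idiff_orig)
        stars.append(res.m_star)
    curves = np.asarray(curves)
    out = pd.DataFrame(
        {
            "m": list(m_grid),
            "idiff_recon_mean": curves.mean(axis=0),
            "idiff_recon_sd": curves.std(axis=0, ddof=0),
        }
    )
    out.attrs["idiff_orig_mean"] = float(np.mean(origs))
    out.attrs["idiff_orig_sd"] = float(np.std(origs, ddof=0))
    out.attrs["m_star_values"] = stars
    return out


def frame_length_sweep(
    sessions: Sequence[SessionTimeSeries],
    frame_grid: Sequence[int],
    m_grid: Sequence[int] | None = None,
    scorer: Callable[[CohortStack], float] | None = None,
    zscore: bool = True,
    outlier_sd: float | None = None,
) -> pd.DataFrame:
    """Optimal I_diff as a function of scan length.

    For each frame count: truncate every session's time series, estimate
    FCs, stack, run the full component sweep, and record the original and
    optimal reconstructed I_diff.
    """
    frame_grid = list(frame_grid)
    t_min = min(s.ts.n_frames for s in sessions)
    if max(frame_grid) > t_min:
        raise ValueError(f"frame grid exceeds shortest session ({t_min} frames)")
    if min(frame_grid) < 3:
        raise ValueError("frame counts below 3 are invalid")
    rows = []
    for t in frame_grid:
        fcs = [
            timeseries_to_fc(truncate_frames(s.ts, t), zscore=zscore, outlier_sd=outlier_sd)
            for s in sessions
        ]
        manifest = pd.DataFrame(
            {
                "subject": [s.subject for s in sessions],
                "visit": [s.visit for s in sessions],
                "condition": [s.condition for s in sessions],
            }
        )
        stack = stack_cohort(manifest, fcs)
        res = sweep_components(stack, m_grid=m_grid, scorer=scorer)
        rows.append(
            {
                "n_frames": t,
                "idiff_orig": res.idiff_orig,
                "idiff_star": res.idiff_star,
                "m_star": res.m_star,
            }
        )
    return pd.DataFrame(rows)
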