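"""Differential identifiability of a test-retest cohort.

The identifiability matrix A holds the Pearson correlation between every
test-session FC vector (rows) and every retest-session FC vector (columns),
with subjects aligned so the diagonal is self-similarity.  From A:

    I_self   = mean(diag A)           within-subject similarity
    I_others = mean(offdiag A)        between-subject similarity
    I_diff   = (I_self - I_others) * 100

I_diff is the differential-identifiability score (in percent points of
correlation); the identification rate is the Finn-style fraction of subjects
whose self-similarity is the strict maximum of their row (test->retest) or
column (retest->test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import CohortStack

__all__ = [
    "IdentResult",
    "identifiability_matrix",
    "idiff",
    "identification_rate",
    "identifiability_from_stack",
]


@dataclass
class IdentResult:
    """Identifiability matrix plus its scalar summaries."""

    A: np.ndarray
    subjects: list
    I_self: float
    I_others: float
    I_diff: float
    id_rate_t2r: float
    id_rate_r2t: float

    @property
    def id_rate(self) -> float:
        """Headline rate: mean of the two directional rates."""
        return 0.5 * (self.id_rate_t2r + self.id_rate_r2t)

    @property
    def self_identifiability(self) -> np.ndarray:
        """Per-subject self-similarity (diagonal of A)."""
        return np.diag(self.A).copy()

    def summary(self) -> dict:
        return {
            "I_self": self.I_self,
            "I_others": self.I_others,
            "I_diff": self.I_diff,
            "id_rate_test_to_retest": self.id_rate_t2r,
            "id_rate_retest_to_test": self.id_rate_r2t,
            "id_rate": self.id_rate,
            "n_subjects": len(self.subjects),
        }


def _columns_by_subject(stack: CohortStack) -> tuple[list, np.ndarray]:
    subjects = stack.subjects
    if stack.sessions["subject"].duplicated().any():
        raise ValueError("stack must hold exactly one session per subject")
    order = {s: k for k, s in enumerate(stack.sessions["subject"])}
    cols = np.array([order[s] for s in subjects])
    return subjects, stack.edge_matrix[:, cols]


def identifiability_matrix(
    test_stack: CohortStack, retest_stack: CohortStack
) -> tuple[np.ndarray, list]:
    """Pearson correlations between test (rows) and retest (columns) sessions.

    Both stacks must hold one session per subject over the same subject set
    and edge order; rows/columns are sorted by subject id so the diagonal is
    self-similarity.
    """
    if test_stack.n_edges != retest_stack.n_edges:
        raise ValueError("edge count mismatch between test and retest stacks")
    subj_t, x = _columns_by_subject(test_stack)
    subj_r, y = _columns_by_subject(retest_stack)
    if subj_t != subj_r:
        raise ValueError("subject sets differ between test and retest stacks")
    for name, m, subj in (("test", x, subj_t), ("retest", y, subj_r)):
        sd = m.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            which = ", ".join(str(subj[i]) for i in bad)
            raise ValueError(f"constant edge vector in {name} session(s) of subject(s) {which}")
    xc = (x - x.mean(axis=0)) / x.std(axis=0)
    yc = (y - y.mean(axis=0)) / y.std(axis=0)
    a = xc.T @ yc / x.shape[0]
    return np.clip(a, -1.0, 1.0), subj_t


def identification_rate(A: np.ndarray, direction: str = "test_to_retest") -> float:
    """Finn-style identification success rate.

    ``test_to_retest``: each row is a query against the retest database;
    success iff the diagonal entry is the strict row maximum.  Ties on the
    maximum involving the diagonal count as failure.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n or n < 2:
        raise ValueError("A must be square with at least 2 subjects")
    if direction == "test_to_retest":
        rows = A
    elif direction == "retest_to_test":
        rows = A.T
    else:
        raise ValueError(f"unknown direction {direction!r}")
    diag = np.diag(rows)
    off = rows.copy()
    np.fill_diagonal(off, -np.inf)
    return float(np.mean(diag > off.max(axis=1)))


def idiff(A: np.ndarray, subjects: list | None = None) -> IdentResult:
    """I_self, I_others, I_diff and identification rates from matrix A."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("identifiability matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 subjects (I_others undefined for N=1)")
    i_self = float(np.mean(np.diag(A)))
    off = ~np.eye(n, dtype=bool)
    i_others = float(np.mean(A[off]))
    return IdentResult(
        A=A,
        subjects=list(subjects) if subjects is not None else list(range(n)),
        I_self=i_self,
        I_others=i_others,
        I_diff=(i_self - i_others) * 100.0,
        id_rate_t2r=identification_rate(A, "test_to_retest"),
        id_rate_r2t=identification_rate(A, "retest_to_test"),
    )


def identifiability_from_stack(
    stack: CohortStack,
    test_visit: str | None = None,
    retest_visit: str | None = None,
    condition: str | None = None,
) -> IdentResult:
    """Full identifiability summary of a 2-visit cohort stack."""
    if condition is None:
        conds = stack.conditions
        if len(conds) != 1:
            raise ValueError("multiple conditions present; pass condition=")
        condition = conds[0]
    sub = stack.select(condition=condition)
    visits = sub.visits
    if test_visit is None or retest_visit is None:
        if len(visits) != 2:
            raise ValueError(f"stack has visits {visits}; pass test_visit/retest_visit")
        test_visit, retest_visit = visits
    a, subjects = identifiability_matrix(
        sub.select(visit=test_visit), sub.select(visit=retest_visit)
    )
    return idiff(a, subjects)
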