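"""Synthetic test-retest FC cohorts with planted fingerprint structure.

Each session's vectorized FC is a sum of variance components in edge space:

    x[subject s, visit v, condition c] = g + f_s + o_c + eps_{s,v,c}

* ``g`` — cohort-level structure shared by every session (a mixture of
  ``n_group_modes`` random edge directions, per-edge SD ``sd_group``);
* ``f_s`` — the subject fingerprint: subject-unique orthogonal mixing
  weights over a shared pool of fingerprint directions (per-edge SD
  ``sd_subject``).  Orthogonal weights keep every subject's fingerprint
  equally strong, so the planted signal rank is well defined and
  recoverable;
* ``o_c`` — a condition (task) offset, drawn only when more than one
  condition is simulated (per-edge SD ``sd_condition``);
* ``eps`` — i.i.d. Gaussian session noise (per-edge SD ``sd_noise``).

All SD parameters are per-edge standard deviations, so their ratios are
comparable at any cohort size.  The whole stack is rescaled by a single
global scalar so values lie in [-1, 1], and columns devectorize to symmetric
matrices with unit diagonal.  Everything is deterministic given the seed.

A behavioral score can be coupled to the fingerprint values at a chosen
random subset of edges, giving downstream association and predictive-model
analyses a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fc import CohortStack, SessionTimeSeries, TimeSeries, devectorize

__all__ = [
    "SyntheticSpec",
    "BehaviorSpec",
    "CohortTruth",
    "BehaviorTruth",
    "generate_cohort",
    "generate_behavior",
    "generate_timeseries_cohort",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic test-retest cohort."""

    n_subjects: int = 50
    n_regions: int = 60
    n_visits: int = 2
    n_group_modes: int = 10
    n_subject_modes_per_subject: int = 1
    sd_group: float = 0.4
    sd_subject: float = 0.3
    sd_noise: float = 0.15
    n_conditions: int = 1
    sd_condition: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_visits < 1 or self.n_conditions < 1:
            raise ValueError("counts must be >= 1")
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.n_group_modes < 0 or self.n_subject_modes_per_subject < 0:
            raise ValueError("mode counts must be >= 0")
        for name in ("sd_group", "sd_subject", "sd_noise", "sd_condition"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def n_sessions(self) -> int:
        return self.n_subjects * self.n_visits * self.n_conditions


@dataclass
class BehaviorSpec:
    """Parameters of the fingerprint-coupled behavioral score."""

    n_coupled_edges: int = 30
    effect_sd: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_coupled_edges < 0:
            raise ValueError("n_coupled_edges must be >= 0")
        if self.effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class CohortTruth:
    """Planted components of a synthetic cohort (after global rescaling)."""

    spec: SyntheticSpec
    group: np.ndarray                  # (E,)
    fingerprints: np.ndarray           # (E, n_subjects), column order = subjects
    condition_offsets: np.ndarray      # (E, n_conditions)
    subjects: list[str]
    conditions: list[str]
    scale: float
    signal_rank: int                   # numerical rank of centered noiseless stack

    def summary(self) -> dict:
        return {
            "scale": self.scale,
            "signal_rank": self.signal_rank,
            "subjects": self.subjects,
            "conditions": self.conditions,
        }


@dataclass
class BehaviorTruth:
    coupled_edges: np.ndarray
    betas: np.ndarray


def _subject_ids(n: int) -> list[str]:
    w = max(3, len(str(n)))
    return [f"sub{i + 1:0{w}d}" for i in range(n)]


def _visit_labels(n: int) -> list[str]:
    return ["test", "retest"] if n == 2 else [f"v{i + 1}" for i in range(n)]


def _condition_labels(n: int) -> list[str]:
    return ["rest"] if n == 1 else [f"task{k + 1:02d}" for k in range(n)]


def generate_cohort(spec: SyntheticSpec) -> tuple[CohortStack, CohortTruth]:
    """Simulate a test-retest cohort stack with known planted structure."""
    rng = np.random.default_rng(spec.seed)
    e = spec.n_edges
    subjects = _subject_ids(spec.n_subjects)
    visits = _visit_labels(spec.n_visits)
    conditions = _condition_labels(spec.n_conditions)

    if spec.n_group_modes > 0 and spec.sd_group > 0:
        gdir = rng.standard_normal((e, spec.n_group_modes))
        group = spec.sd_group * gdir.sum(axis=1) / np.sqrt(spec.n_group_modes)
    else:
        group = np.zeros(e)

    pool = spec.n_subjects * spec.n_subject_modes_per_subject
    if pool > 0 and spec.sd_subject > 0:
        phi = rng.standard_normal((e, pool))
        # subject-unique orthonormal mixing weights over the shared pool
        q, _ = np.linalg.qr(rng.standard_normal((pool, spec.n_subjects)))
        fingerprints = spec.sd_subject * (phi @ q)
    else:
        fingerprints = np.zeros((e, spec.n_subjects))

    if spec.n_conditions > 1 and spec.sd_condition > 0:
        offsets = spec.sd_condition * rng.standard_normal((e, spec.n_conditions))
    else:
        offsets = np.zeros((e, spec.n_conditions))

    # session order matches stack_cohort's canonical (subject, condition, visit)
    rows = []
    cols_signal = []
    for s in range(spec.n_subjects):
        for c in range(spec.n_conditions):
            for v in range(spec.n_visits):
                rows.append((subjects[s], visits[v], conditions[c]))
                cols_signal.append(group + fingerprints[:, s] + offsets[:, c])
    signal = np.column_stack(cols_signal)
    noise = spec.sd_noise * rng.standard_normal(signal.shape)
    x = signal + noise

    scale = max(1.0, float(np.max(np.abs(x)))) if x.size else 1.0
    x = x / scale

    centered_signal = signal / scale
    centered_signal = centered_signal - centered_signal.mean(axis=0)
    signal_rank = int(np.linalg.matrix_rank(centered_signal)) if np.any(centered_signal) else 0

    sessions = pd.DataFrame(rows, columns=["subject", "visit", "condition"])
    stack = CohortStack(edge_matrix=x, sessions=sessions, n_regions=spec.n_regions)
    truth = CohortTruth(
        spec=spec,
        group=group / scale,
        fingerprints=fingerprints / scale,
        condition_offsets=offsets / scale,
        subjects=subjects,
        conditions=conditions,
        scale=scale,
        signal_rank=signal_rank,
    )
    return stack, truth


def generate_behavior(
    stack: CohortStack, bspec: BehaviorSpec, truth: CohortTruth
) -> tuple[pd.Series, BehaviorTruth]:
    """Behavioral scores linearly coupled to fingerprint values at random edges.

    score_s = sum over coupled edges of beta_e * fingerprint[e, s] + noise,
    with beta_e ~ N(0, effect_sd^2) and noise ~ N(0, noise_sd^2).
    """
    if len(stack.subjects) < 2:
        raise ValueError("need at least 2 subjects")
    e = stack.n_edges
    if bspec.n_coupled_edges > e:
        raise ValueError(f"n_coupled_edges={bspec.n_coupled_edges} exceeds edge count {e}")
    rng = np.random.default_rng(bspec.seed)
    coupled = np.sort(rng.choice(e, size=bspec.n_coupled_edges, replace=False))
    betas = bspec.effect_sd * rng.standard_normal(bspec.n_coupled_edges)
    signal = truth.fingerprints[coupled, :].T @ betas  # (n_subjects,)
    noise = bspec.noise_sd * rng.standard_normal(len(truth.subjects))
    scores = pd.Series(signal + noise, index=pd.Index(truth.subjects, name="subject"), name="score")
    return scores, BehaviorTruth(coupled_edges=coupled, betas=betas)


def _nearest_correlation(a: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite correlation matrix closest to ``a``."""
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    w = np.maximum(w, eps)
    s = (v * w) @ v.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def generate_timeseries_cohort(
    spec: SyntheticSpec, n_frames: int = 300
) -> tuple[list[SessionTimeSeries], CohortTruth]:
    """Regional time series whose sample FCs carry the planted structure.

    Each subject's noiseless signal FC (group + fingerprint, devectorized
    and projected to the nearest positive-definite correlation matrix) is
    the population covariance; every visit samples ``n_frames`` i.i.d.
    Gaussian frames from it.  Session-to-session variability therefore comes
    purely from correlation sampling error, which shrinks as frames are
    added — emulating the effect of scan length on FC estimates.
    """
    if spec.n_conditions != 1:
        raise ValueError("time-series cohorts support a single condition")
    noiseless = SyntheticSpec(**{**vars(spec), "sd_noise": 0.0})
    stack, truth = generate_cohort(noiseless)
    rng = np.random.default_rng(spec.seed + 1_000_003)
    visits = _visit_labels(spec.n_visits)
    sessions: list[SessionTimeSeries] = []
    for s, subj in enumerate(truth.subjects):
        col = truth.group + truth.fingerprints[:, s]
        sigma = _nearest_correlation(devectorize(col, spec.n_regions).values)
        chol = np.linalg.cholesky(sigma)
        for v in visits:
            frames = chol @ rng.standard_normal((spec.n_regions, n_frames))
            sessions.append(
                SessionTimeSeries(subject=subj, visit=v, ts=TimeSeries(frames), condition="rest")
            )
    return sessions, truth
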