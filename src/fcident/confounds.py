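"""Association of self-identifiability with a per-subject confound.

Head motion is the usual suspect: if subjects who move more are also easier
(or harder) to identify, the fingerprint may partly reflect motion rather
than neural idiosyncrasy.  The per-subject predictor is the maximum of the
confound over the two visits; the response is the subject's
self-identifiability (diagonal of the identifiability matrix).  Both a
linear and a log10-linear ordinary-least-squares trend are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .identifiability import IdentResult

__all__ = ["ConfoundAssoc", "self_identifiability_vs_confound"]


@dataclass
class FitLine:
    slope: float
    intercept: float
    r: float
    p: float


@dataclass
class ConfoundAssoc:
    linear: FitLine
    log10_linear: FitLine | None
    n_subjects: int

    def summary(self) -> dict:
        out = {
            "n_subjects": self.n_subjects,
            "linear": vars(self.linear).copy(),
        }
        out["log10_linear"] = vars(self.log10_linear).copy() if self.log10_linear else None
        return out


def _ols(x: np.ndarray, y: np.ndarray) -> FitLine:
    if np.std(x) == 0:
        raise ValueError("confound has zero variance: correlation undefined")
    res = stats.linregress(x, y)
    return FitLine(slope=float(res.slope), intercept=float(res.intercept),
                   r=float(res.rvalue), p=float(res.pvalue))


def self_identifiability_vs_confound(
    ident: IdentResult, confound_per_visit: pd.DataFrame, log10: bool = True
) -> ConfoundAssoc:
    """OLS trends of self-identifiability on a per-subject confound.

    ``confound_per_visit`` needs columns ``subject``, ``visit``, ``value``;
    every subject in the identifiability result must appear for both visits.
    The predictor is the per-subject maximum over visits.  The log10-linear
    fit requires strictly positive confounds; offenders are named in the
    error.  Pass ``log10=False`` to fit the linear trend only.
    """
    df = confound_per_visit
    required = {"subject", "visit", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"confound table must have columns {sorted(required)}")
    per_subj = df.groupby("subject")["value"].max()
    missing = [s for s in ident.subjects if s not in per_subj.index]
    if missing:
        raise ValueError(f"confound missing for subjects: {missing}")
    n_visits = df.groupby("subject")["visit"].nunique()
    short = [s for s in ident.subjects if n_visits.get(s, 0) < 2]
    if short:
        raise ValueError(f"confound missing a visit for subjects: {short}")
    x = per_subj.loc[ident.subjects].to_numpy(dtype=float)
    y = ident.self_identifiability
    linear = _ols(x, y)
    log_fit = None
    if log10:
        nonpos = [s for s, v in zip(ident.subjects, x) if v <= 0]
        if nonpos:
            raise ValueError(f"log10-linear fit needs positive confounds; offending subjects: {nonpos}")
        log_fit = _ols(np.log10(x), y)
    return ConfoundAssoc(linear=linear, log10_linear=log_fit, n_subjects=len(ident.subjects))
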