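# Methods

## Model and procedure

`fcident` treats a test-retest cohort of functional connectomes as an
edges × sessions matrix **X**: the strict upper triangle of each session's
symmetric FC (Pearson correlations between regional time courses) is
vectorized in a fixed row-major order and placed in one column.

**Centering convention.** Each *column* is centered by its own mean over
edges (µ_k), and µ_k is added back after reconstruction. This is the opposite
of the per-feature centering most PCA libraries apply: here the sessions are
the variables and the edges the observations. The convention matters — it
makes the per-session mean connectivity exactly invariant under
reconstruction at any m (asserted in the tests), so reconstruction can never
shift a session's overall connectivity level, only redistribute it.

**Decomposition.** An economy SVD of the centered matrix, X_c = U S Vᵀ,
yields orthonormal edge-space eigenvectors ("connectivity modes", columns of
U) ranked by explained variance. The SVD route is used rather than an
eigendecomposition of the session covariance for numerical stability; the
tests verify equivalence against an independent Gram-matrix
eigendecomposition up to 50×20 and against scikit-learn's PCA on the
explained-variance spectrum. Eigenvector sign is arbitrary; we fix it by
making each mode's largest-magnitude element positive so runs are exactly
reproducible.

**Reconstruction and scoring.** Reconstruction at m keeps the m
highest-variance modes and restores µ_k. The quality function is the
differential identifiability I_diff(m) = (I_self − I_others)·100 computed
from the test-retest identifiability matrix of the reconstructed stack;
m* is the argmax over a component grid, with ties resolved to the smallest m
(parsimony). The default grid is {2, 5, 10, 20, …, 160}, clipped to the
number of sessions. Explained variance reported for a reconstruction is the
cumulative ratio on the *centered* data (the uncentered alternative would
also count the session means, which reconstruction preserves by construction
at every m, making it uninformative).

**Identification rate.** Finn-style matching: a test session is correctly
identified if its correlation with the same subject's retest session is the
strict row maximum of the identifiability matrix. Ties count as failures
(conservative). Both query directions are computed; the headline rate is
their mean.

**Edgewise ICC.** One-way random-effects ICC(1,1),
(MS_between − MS_within)/(MS_between + (k−1)·MS_within), vectorized over
edges; the two-way absolute-agreement ICC(A,1) is available as a variant.
ICC(1,1) is the standard test-retest choice and requires no rater-effect
model — sessions are exchangeable ratings. Negative values are retained
(they are informative: within-subject disagreement exceeding between-subject
variance); zero-variance edges yield NaN and are excluded from summaries.
For task identifiability the conditions are the groups and subjects the
ratings; when a condition has several visits the per-subject average FC is
the rating by default (a single designated visit is configurable). "Highly
identifiable" edges for nodal density are operationalized as those above the
95th percentile of the empirical ICC distribution — no parametric test.

**Association robustness.** Edgewise Pearson correlation of connectivity
with a behavioral score across subjects; edges with two-sided p < α (default
0.01) are kept, then only the connected component(s) with the most nodes
(node-count ties keep the union — deterministic and conservative toward
robustness). Robustness is the edge/node count of the test∩retest
intersection, ranked against a null built by shuffling the scores (one
shuffle applied to both visits per iteration). Percentile = fraction of null
values strictly below the observed count, ×100. Internally all permutations'
correlations are computed in a single matrix product and thresholded at the
critical |r| equivalent to p < α, which is decision-identical to computing
per-permutation p-values.

**CPM.** Within every leave-one-out fold, candidate edges are those
positively and significantly (p < α) correlated with the score in the
training subjects, ranked by r × max(ICC, 0) — the product is our
operationalization of "correlation weighted by ICC"; the ICC floor keeps
unreliable edges from being promoted by a negative-times-negative artifact.
The top-k edge values are summed into a strength score and a univariate
linear model predicts the held-out subject. Selection is re-estimated inside
each fold to avoid leakage; `rank_on_full=True` reproduces the leaky variant
for comparison. Predictability is corr(predicted, observed) per k over
k ∈ {5, 10, …, 100}.

## The synthetic generator

Each session's edge vector is g + f_s + o_c + ε:

| component | default | meaning |
|---|---|---|
| g (group) | sd_group = 0.4 | mixture of n_group_modes = 10 random edge directions, shared by all sessions |
| f_s (fingerprint) | sd_subject = 0.3 | subject-unique orthogonal mixing weights over a shared direction pool |
| o_c (condition) | sd_condition = 0.2 | per-condition offset, drawn only when n_conditions > 1 |
| ε (noise) | sd_noise = 0.15 | i.i.d. Gaussian per edge and session |

All SDs are *per-edge* standard deviations, so their ratios mean the same
thing at any parcellation size (a unit-norm convention would make "signal vs
noise" depend on the edge count). The fingerprint weights are scaled columns
of a Haar-orthogonal matrix rather than i.i.d. Gaussians: i.i.d. weights give
a Marchenko-Pastur spread whose weakest fingerprint dimensions fall below
the noise floor, making the planted dimensionality unrecoverable by any
method; orthogonal weights keep every subject's fingerprint equally strong
and the ground truth well defined. The stack is rescaled by one global
scalar (never per column, which would distort relative structure) so values
lie in [−1, 1], and the ground-truth record stores the rescaled components
plus the numerical rank of the centered noiseless stack — the quantity the
component sweep should recover.

The default variance ratios give I_self ≈ 0.92 and I_others ≈ 0.59, close to
published resting-state test-retest values. Two structural properties of
this i.i.d.-noise model are worth knowing when interpreting results:

1. **Held-out projection gains are small by construction.** For a basis
   estimated on training sessions and applied to fresh sessions of the same
   subjects, the best possible I_diff gain is ≈ 100·σ_s²(1/σ_signal² −
   1/σ_total²), while subspace-estimation error costs ≈ I_diff·(sd_noise /
   sd_subject)²-order losses. Net improvement therefore requires a
   fingerprint-dominant regime, roughly sd_subject² ≳ 0.4·(sd_group² +
   sd_noise²); the defaults sit inside it. Real session noise is partly
   structured (shared artifact directions), which is what makes validation
   gains larger on real data than this generator can show.
2. **Within-sample denoising is capped at the tail share.** Reconstruction
   at m* removes only the noise outside the kept subspace, a fraction
   ≈ 1 − m*/S of the in-span noise; with two visits per subject that is
   about half.

Behavioral scores are Σ_e β_e·f[e, s] + η over a random edge subset
(defaults: 30 coupled edges, β ~ N(0, 1), score noise SD 0.05). Coupling to
the *fingerprint* component (not the noisy observed values) makes the
planted association a stable subject trait. Because reconstruction's CPM
advantage is mediated entirely by session noise, the behavior-prediction
analyses are run on noisier cohorts (sd_noise = 0.3, I_self ≈ 0.8, 100
subjects — session quality and cohort size typical of the data such studies
use); in the low-noise default regime the original and reconstructed
predictability curves are statistically indistinguishable, which the tests
would misread as a method failure when it is a ceiling effect.

Time-series cohorts (for scan-length analyses) sample multivariate Gaussian
frames from each subject's noiseless signal FC projected to the nearest
positive-definite correlation matrix; session-to-session variability then
comes purely from correlation sampling error, which is the phenomenon the
frame-count sweep studies. The generator does **not** emulate BOLD
autocorrelation, spatially structured motion artifacts, shared low-rank
session noise, or heavy-tailed edge distributions — passing tests show the
pipeline recovers planted linear-Gaussian structure, not that it is robust
to those realities.

## Numerical conventions and degenerate inputs

- Canonical edge order: row-major strict upper triangle, 0-based internally.
- Symmetry tolerance on FC input: 1e-8; round-trip overflow beyond |1| is
  clipped only within 1e-12.
- Odd-length session splits give the extra frame to the second half.
- Outlier exclusion in FC estimation is pairwise-complete: a flagged frame is
  dropped only for pairs involving the flagged region (preserves maximal
  data).
- Constant time courses, constant edge vectors, constant scores and
  zero-variance confounds are hard errors naming the offending region,
  session or subject — silent NaN propagation is reserved for per-edge ICC
  only.
- All randomness flows through numpy Generators seeded from explicit seeds;
  CLI outputs are written at 12 significant digits and are byte-identical
  across runs at a fixed seed.
- Argmax ties: smallest m in sweeps; failure in identification; union of
  tied components in giant-component filtering; stable sorts everywhere a
  ranking is reported.

## Problem sizes

The test suite and the acceptance script run on cohorts of 20–100 subjects
and 10–80 regions (up to ~3,200 edges), 20 seeds per simulation-based check
and 100–200 permutations/null cohorts per calibration check — sizes at which
every planted effect is comfortably detectable while a full run stays within
a couple of minutes on one CPU. The algorithms themselves are vectorized
over edges and scale to full-resolution parcellations (tens of thousands of
edges) without modification.

## Known limitations

- ICC variants beyond ICC(1,1)/ICC(A,1) (e.g. consistency ICC(C,1)) are not
  implemented.
- The CPM implementation is the classic positive-network, summed-strength,
  univariate-fit variant under LOOCV only.
- `bootstrap_sweep` subsamples subjects without replacement; with
  subset sizes close to the cohort size the resample curves are strongly
  dependent, so the reported SD understates true sampling variability.
- Component selection is a contiguous prefix of the variance ranking;
  non-contiguous subset selection is out of scope.
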