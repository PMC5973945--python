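# fcident

Differential identifiability of functional connectomes via group-level PCA
reconstruction.

## The problem

A functional connectome (FC) is the matrix of Pearson correlations between
regional BOLD time courses. Test-retest studies show each person's FC carries
an individual *fingerprint*: two sessions of the same subject correlate more
with each other than with anyone else's. Session noise blurs that fingerprint.
`fcident` implements a group-level strategy to sharpen it: stack the
vectorized FCs of a cohort, decompose them into ranked *connectivity modes*
(edge-space principal components), and reconstruct each individual FC from
only the first m modes. High-variance modes carry cohort-level structure,
intermediate ones the subject fingerprint, and the tail mostly session noise
— so there is an optimal m.

The package is aimed at researchers working with parcellated test-retest fMRI
cohorts (or any repeated-measures network data with the same structure) who
want to quantify and maximize subject identifiability, and at methodologists
who need a controlled synthetic test bed for fingerprint analyses.

## The statistic

Let **A** be the identifiability matrix, a_ij = corr(test FC of subject i,
retest FC of subject j). With

    I_self   = ⟨a_ii⟩        (within-subject similarity)
    I_others = ⟨a_ij⟩, i≠j   (between-subject similarity)

the **differential identifiability** of the cohort is

    I_diff(m) = (I_self − I_others) · 100

evaluated on FCs reconstructed from m modes, and the working point is

    m* = argmax_m I_diff(m).

Around this core the package provides the downstream fingerprint analyses:
Finn-style identification rates; edgewise intraclass correlation ICC(1,1)
(subjects as groups, sessions as ratings — or tasks as groups, subjects as
ratings) with functional-network block summaries and nodal densities;
robustness of FC-behavior association graphs (p < α edges, giant component,
test∩retest intersection, permutation null); ICC-weighted connectome-based
predictive modeling (CPM) under leave-one-out cross-validation; and
linear/log10-linear trends of self-identifiability against a motion-proxy
confound. A seeded synthetic-cohort generator with known group, fingerprint
and noise components supplies ground truth for all of it.

## Worked example

```python
import numpy as np
from fcident import (SyntheticSpec, generate_cohort, decompose, sweep_components,
                     reconstruct, identifiability_from_stack, edgewise_icc)

spec = SyntheticSpec(n_subjects=30, n_regions=40, seed=7)
stack, truth = generate_cohort(spec)          # edges x sessions + ground truth
basis = decompose(stack)                      # group-level PCA (ConnectomePCA)
sweep = sweep_components(stack, basis=basis)  # I_diff over the m grid
print(f"planted signal rank : {truth.signal_rank}")
print(f"optimal m*          : {sweep.m_star}")
print(f"I_diff original     : {sweep.idiff_orig:.2f}")
print(f"I_diff at m*        : {sweep.idiff_star:.2f}")
recon = reconstruct(basis, stack, sweep.m_star)
orig, rec = identifiability_from_stack(stack), identifiability_from_stack(recon)
print(f"identification rate : {orig.id_rate:.2f} -> {rec.id_rate:.2f}")
frac = np.mean(edgewise_icc(recon).values > edgewise_icc(stack).values)
print(f"edges with ICC gain : {100*frac:.1f}%")
```

Output:

```
planted signal rank : 30
optimal m*          : 30
I_diff original     : 32.65
I_diff at m*        : 38.04
identification rate : 1.00 -> 1.00
edges with ICC gain : 100.0%
```

The sweep recovers the planted dimensionality exactly (30: the dimension
spanned by the shared group component plus the 30 subject fingerprints —
the generator records the exact value in its ground-truth record),
reconstruction at m* raises I_diff by ~5 percentage points of correlation,
and every edge becomes more reliable (higher ICC) after denoising.

The same workflows are available from the command line:

```bash
fcident simulate --subjects 30 --regions 40 --seed 7 --out cohort/
fcident sweep --manifest cohort/manifest.csv --out results/sweep
fcident icc --manifest cohort/manifest.csv --out results/icc
```

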