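# rhopca

Contrastive dimension reduction by Rayleigh-quotient maximization (ρPCA),
with a contrastive-PCA (cPCA) baseline, a single-cell-style count
preprocessing chain, planted-axis simulators, and per-group variance-ratio
reporting.

## The problem

Given a *target* dataset (the condition of interest — say, nuclei from
female mice) and a *background* dataset (a control — nuclei from males),
we want directions along which the target varies strongly while the
background does not. Let Σ̂T and Σ̂B be the sample covariances of the two
groups on a shared feature set. For a direction v, the Rayleigh quotient

    ρ(v) = (vᵀ Σ̂T v) / (vᵀ Σ̂B v)

is the target-to-background variance ratio along v. Maximizing ρ is
equivalent to maximizing vᵀΣ̂Tv subject to vᵀΣ̂Bv = 1, whose stationary
points solve the symmetric-definite generalized eigenproblem

    Σ̂T v = λ Σ̂B v.

The top-d generalized eigenvectors (GEs) V satisfy VᵀΣ̂BV = I (orthonormal
in the background inner product), and each eigenvalue λᵢ *is* the variance
ratio along GE i — an exact, parameter-free, and interpretable solution.
cPCA instead eigendecomposes Cα = Σ̂T − αΣ̂B for a tunable α; linearizing
1/x in ρ(v) shows cPCA is a first-order approximation of the quotient,
which is why it needs α tuning while the generalized eigenproblem does not.
When Σ̂B is singular (more features than background samples), additive
Tikhonov shrinkage Σ̂B + μI restores definiteness while perturbing large
eigenvalues only slightly.

## Worked example

```python
import numpy as np
from rhopca import RhoPCA, default_scenario, simulate_contrastive

# 10-dim Gaussians: two axes of variance 10 shared by both groups, one
# axis of variance 10 present only in the target, unit noise elsewhere
sc = default_scenario(dim=10, n=300, seed=1)
x_t, x_b = simulate_contrastive(sc)
res = RhoPCA.from_data(x_t, x_b).fit(n_components=3)
print(res.summary())
```

prints

```
rhoPCA fit
================================================================
features:            10
components retained: 3
regularization mu:   0
n target / background: 300 / 300
----------------------------------------------------------------
component  eigenvalue (target/background variance ratio)
  GE1       9.73389
  GE2       1.52338
  GE3       1.37953
----------------------------------------------------------------
top 3 loadings per component:
  GE1: f2 (+1.025), f3 (+0.187), f7 (-0.089)
  GE2: f8 (+0.619), f7 (-0.516), f3 (-0.335)
  GE3: f4 (+0.595), f9 (-0.519), f8 (-0.452)
```

GE 1 recovers the planted target-only axis (feature `f2`) with eigenvalue
≈ 10: along that direction the target has about ten times the background's
variance. The shared axes are suppressed to ratios near 1. With real data,
`res.report.group_ratios` localizes which labelled group (e.g. cell type)
drives each component, and `res.top_loadings(k)` lists the features behind
it.

The same workflow runs from the shell:

```sh
rhopca simulate --out fixture --dim 30 --n 1000 --seed 1
rhopca fit --target fixture/target.csv --background fixture/background.csv \
           --out run --d 2 --no-scale
rhopca report --run run
```

For raw count matrices, `rhopca fit --preprocess` first filters features to
the 80th percentile of total counts, depth-normalizes each cell to 10,000
counts, applies log1p, keeps the 2,000 most highly variable features
(binned-dispersion z-scores computed on the target group), and
standard-scales each group separately so both covariances are correlation
matrices.

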