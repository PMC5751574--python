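# dragonclust

Divisive hierarchical maximum-likelihood clustering (DRAGON) for
sample-by-feature matrices such as bulk or single-cell expression tables and
binarised mutation profiles, aimed at the low-dimensional regime (a handful
of top-ranked genes, d < n).

Most divisive hierarchical methods search over subset splits, which is
exponential in the number of samples. DRAGON instead peels **one cluster at a
time** by removing **one sample at a time**: given the current candidate set
χ_s with n members in d dimensions, its Gaussian log-likelihood under its own
maximum-likelihood fit has the closed form

    L = -(1/2) n d - (n d / 2) log 2π - (n / 2) log|Σ|,

with Σ the divisor-n scatter matrix. Removing a sample x̂ updates everything
exactly in O(d²):

    μ* = μ - (x̂ - μ)/(n - 1)
    Σ* = n/(n-1) Σ - n/(n-1)² (x̂ - μ)(x̂ - μ)ᵀ
    |Σ*| = (n/(n-1))^d |Σ| (1 - P/(n-1)),   P = (x̂ - μ)ᵀ Σ⁻¹ (x̂ - μ)

so the sample whose removal maximally increases L is simply the one with the
largest squared Mahalanobis distance P (for members, 0 ≤ P ≤ n − 1). Removals
continue while they increase L; the surviving set is then refined by an exact
two-group 1-D k-means on Euclidean distances to its centroid, taken out of
the sample set, and the procedure repeats. Extracting a cluster of size n₁
from n samples costs exactly (1/2)(n − n₁)(n + n₁ + 1) candidate
evaluations — O(n²) per cluster instead of O(2ⁿ).

When the number of clusters c is unknown it is estimated from the total
log-likelihood L_t(c) = Σᵢ Lᵢ: the successive gains δL_t(k) = L_t(k+1) −
L_t(k) are min-max normalised, and c is the first k whose normalised gain
falls below a threshold τ (default 0.10) — the elbow of the curve.

The package also ships the surrounding experiment machinery: a seeded
Gaussian-mixture benchmark generator, matched clustering accuracy (optimal
one-to-one cluster/class assignment), the Rand index, and chi-squared
feature ranking for choosing the top-d genes.

## Worked example

```python
import numpy as np
from dragonclust import (SyntheticSpec, make_gaussian_mixture,
                         DragonConfig, dragon_fit, matched_accuracy, estimate_c)

X, y = make_gaussian_mixture(SyntheticSpec(d=2, n_clusters=4,
                                           n_per_cluster=100,
                                           separation=8.0, seed=0))
result = dragon_fit(X, DragonConfig(n_clusters=4))
report = matched_accuracy(y, result.labels)
print("cluster sizes:", np.bincount(result.labels))
print("total log-likelihood: %.1f" % result.total_loglik)
print("matched accuracy: %.1f%%" % (100 * report.matched_accuracy))
curve = estimate_c(X, DragonConfig(max_clusters=6))
print("normalised likelihood gains:", np.round(curve.dlt_norm, 3))
print("estimated number of clusters:", curve.chosen_c)
```

prints

```
cluster sizes: [102  99  99 100]
total log-likelihood: -1134.0
matched accuracy: 99.5%
normalised likelihood gains: [0.683 1.    0.537 0.002 0.   ]
estimated number of clusters: 4
```

Four clusters of ~100 samples are recovered almost exactly (99.5% of samples
match the generating labels under the best one-to-one matching), and the
likelihood curve's normalised gain collapses after k = 4, so the elbow rule
picks c = 4. Recovery on mixtures of *equal-density* clusters is
seed-dependent — see `docs/methods.md` for why the extraction walk can
straddle two equally dense clusters — so a single good seed like this one is
not representative of the average case.

The same pipeline from the shell:

```sh
dragon simulate --d 2 --clusters 4 --n-per-cluster 100 --seed 0 --output-prefix sim
dragon cluster  --input sim.matrix.tsv --clusters 4 --output-prefix run
dragon evaluate --true sim.labels.txt --pred run.labels.txt
dragon rank     --input sim.matrix.tsv --labels sim.labels.txt --top 2
```

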