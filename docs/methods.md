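# Methods

## Model and procedure

A candidate cluster χ_s (n samples, d features, d < n) is modelled as a
single Gaussian fitted by maximum likelihood to its own members. Because the
fitted covariance Σ is the divisor-n scatter of exactly those members, the
quadratic term of the log-likelihood collapses (tr(Σ⁻¹ · nΣ) = nd) and

    L(χ_s) = -(1/2) n d - (n d / 2) log 2π - (n / 2) log|Σ|.

L depends on the data only through n, d and log|Σ|. Priors over clusters are
omitted throughout: a single cluster is extracted at a time, so a mixing
proportion would add a constant.

**Extraction.** Starting from the whole active set, the sample whose removal
maximally increases L is removed, repeatedly, while any removal increases L
strictly and the set stays above `min_cluster_size`. The removal score is
the squared Mahalanobis distance P = (x − μ)ᵀΣ⁻¹(x − μ): the likelihood
change on removal is

    ΔL = -(1/2)log|Σ| + ((n-1)/2)log(1 - P/(n-1))
         + ((n-1)d/2)log(n/(n-1)) - d/2 - (d/2)log 2π,   L* = L - ΔL,

which is strictly decreasing in P, so argmax P, argmax L* and argmin ΔL
coincide; the implementation evaluates P for all n members per step and the
acceptance suite verifies the equivalence exhaustively. For members of a
divisor-n fit, P ≤ n − 1 with equality when one sample carries an entire
direction of the scatter.

**Exact downdating.** Mean, covariance, determinant, inverse and likelihood
are maintained incrementally: μ and Σ by their closed-form downdates, |Σ| by
the rank-one determinant identity |Σ*| = (n/(n-1))^d |Σ| (1 − P/(n−1)), and
Σ⁻¹ by a Sherman–Morrison update of the scaled inverse, giving O(d²) per
removal. Every 50 downdates — or whenever the determinant factor drops below
1e−8, where the rank-one update loses precision — the inverse and
log-determinant are refactorised from Σ directly. The acceptance suite
checks all of these against from-scratch refits at 1e−8 relative tolerance
over a thousand random instances.

**Refinement.** The extracted core fixes a centroid μ_s; every sample still
in the active set is mapped to its Euclidean distance d_x from μ_s, and the
1-D values {d_x} are split into two groups by the *exact* two-cluster 1-D
k-means (scan of all n − 1 sorted splits minimising within-group sum of
squares — deterministic and globally optimal, unlike Lloyd iterations). The
low-distance group becomes the cluster. The pass is run `refine_iters` times
(default 2), recomputing μ_s between passes. Refinement may re-admit samples
removed during extraction but never samples already assigned to earlier
clusters. If the split would leave fewer than `min_cluster_size` members the
pre-refinement set is kept (logged); the degenerate all-equal-distance case
returns the active set unchanged.

**Peeling and model selection.** Each refined cluster is removed from the
active set; after c − 1 extractions the remainder forms the last cluster.
Per-cluster likelihoods L_i are computed on the final (post-refinement)
memberships and summed into L_t(c). For unknown c, the algorithm is run for
c = 1…C, the successive gains δL_t(k) = L_t(k+1) − L_t(k) are min-max
normalised onto [0, 1], and the chosen c is the smallest k with normalised
gain below τ; if none, C is returned with a warning, and infeasible c values
truncate the search.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_clusters` | `"auto"` | number of clusters c, or estimate via the elbow rule |
| `max_clusters` | 8 | largest c searched when auto (C) |
| `refine_iters` | 2 | distance-partition passes per cluster |
| `tau` | 0.10 | elbow threshold on the normalised gain (dimensionless, [0,1]) |
| `min_cluster_size` | max(d+2, 3) | smallest cluster during extraction; below d+1 samples the scatter is singular by construction |
| `eps_det` | 1e−12 | floor on the determinant factor 1 − P/(n−1) before its log |
| `refactor_every` | 50 | rank-one downdates between full refactorisations |

Numerical choices: all likelihoods in natural log; ties in argmax P resolve
to the smallest member index (member lists kept sorted), making the whole
deterministic path reproducible bit-for-bit; when a candidate's determinant
factor falls below `eps_det` its ΔL is treated as −∞ (removal maximally
favoured) with a logged warning — this happens when one member sits at the
P = n − 1 bound, i.e. carries a whole direction of the scatter, and removing
it is the only sensible continuation; a near-singular Σ (smallest eigenvalue
below 1e−10 of the largest) receives a recorded ridge λ = 1e−8 · tr(Σ)/d.

## Synthetic benchmark

`synthdata` draws 4 spherical Gaussian clusters of 100 samples each (400
total), with centres on the vertices of the smallest integer cube embedded
in the leading coordinates — for 4 clusters in d ≥ 2, the corners of a
square — scaled so adjacent centres are `separation` (default 8)
within-cluster standard deviations apart. Rows are shuffled with the seed;
identical specs give bit-identical data. `replicate_experiment` sweeps the
dimension and repeats over seeds (20 by default in the acceptance run, with
d ∈ {2, 5, 10} to keep a laptop-scale runtime; the generator itself supports
d up to 30 and beyond).

What the generator does *not* emulate: heavy tails, correlated features,
unequal cluster sizes or densities, and the discreteness of real mutation
matrices. Passing tests on this generator therefore demonstrate correctness
of the machinery and behaviour on idealised well-separated Gaussian data,
not performance on real expression tables.

## Known limitations

**The extraction walk is density-seeking, and frustrated by equal-density
clusters.** The removal score is Mahalanobis distance under the candidate
set's *own* covariance. Whitening by that covariance normalises the
between-cluster axes away, so the walk does not preferentially peel a far
cluster; it contracts the set roughly uniformly in whitened space. Two
consequences, both verified against brute-force refit oracles (the greedy
path is reproduced step-for-step, so they are properties of the equations,
not of this implementation):

1. On data of order-1 scale the likelihood keeps increasing along the walk —
   trimming outliers shrinks |Σ| faster than the n-prefactor loses — so the
   walk rarely stops at a natural cluster boundary and instead terminates in
   a small dense core (or at `min_cluster_size`). The stopping rule is
   scale-sensitive: L is not invariant under rescaling the data, and only
   for small absolute |Σ| does the stop trigger early.
2. Where that core lands decides everything, since refinement builds the
   cluster around the core's centroid. When one cluster is denser than the
   rest the core reliably lands inside it and recovery is near-perfect (the
   method tracks the highest-density cluster; measured mean matched accuracy
   0.88–0.98 on mixtures with per-cluster standard deviations
   0.5/0.8/1.1/1.4 at separation 8). When all clusters are *equally* dense,
   the core's position is decided by sampling noise and can settle into a
   thin, near-degenerate filament straddling two clusters — such
   configurations have tiny |Σ|, hence high likelihood — after which
   refinement merges those two clusters. On equal-density spherical
   4-cluster mixtures at separation 8 the measured mean matched accuracy is
   ~0.45–0.75 depending on dimension and seed, and the elbow estimate of c
   is correspondingly unreliable.

Practical advice following from this: the method is best suited to data with
a density ordering among clusters (common in practice), and benefits from
feature selection that sharpens density contrast; on suspected
equal-density data, compare several runs on feature subsets or perturbed
data and treat disagreement as a warning.

Other limitations: Gaussian component densities only; Euclidean refinement
distance only (no kernels); no dendrogram down to singletons; adding samples
back is done by refitting, not incremental updating; d must stay below the
smallest cluster size or the ridge dominates the fit.
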