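# Methods

## Model

The genome is tiled into fixed-size bins (default 100 kb). Normalized
inter-chromosomal Hi-C contacts define a weighted undirected graph
G = [V, E]: nodes are bins, the weight w_ij of an edge is the
normalized contact count between bins on *different* chromosomes.
Intra-chromosomal contacts are dropped at parse time — the working
hypothesis is that bins belonging to the same nuclear sub-compartment
contact each other preferentially even across chromosomes, so the
inter-chromosomal graph isolates compartment signal from the strong
genomic-distance decay that dominates intra-chromosomal maps.

Bins are embedded in R^d with LINE, which preserves two proximity
notions:

* **First order** — the edge itself. The model probability of an edge
  is p1(v_i, v_j) = sigma(u_i · u_j), fitted against the empirical
  edge distribution w_ij / W by minimizing
  O1 = −Σ_(i,j)∈E w_ij log p1(v_i, v_j).
* **Second order** — shared neighborhoods. Each node also has a
  context vector u'_i; the probability that node i "generates" context
  j is the softmax p2(v_j | v_i) = exp(u'_j · u_i) / Σ_k exp(u'_k · u_i),
  fitted against w_ij / d_i (d_i = weighted degree) by minimizing
  O2 = −Σ w_ij log p2(v_j | v_i) over directed edge copies.

Both objectives are optimized by stochastic gradient descent over
weighted edge draws (alias method, O(1) per draw) with negative
sampling: each positive update is paired with K noise nodes drawn with
probability ∝ d_i^0.75 (the word2vec/LINE convention; the choice is
not critical at our graph sizes). **Joint** mode optimizes
O3 = (1−α) O1 + α O2 by choosing, per edge draw, a first-order update
with probability 1−α and a second-order one otherwise — equal to the
mixed objective in expectation at constant per-sample cost.
**Separate** mode trains each order independently at full dimension,
L2-normalizes each representation row-wise (so neither order dominates
Euclidean k-means) and concatenates to 2d.

k-means (k-means++ seeding, best of n_init = 10 restarts) groups the
embedded bins into sub-compartments C1..Ck. Bins with no
inter-chromosomal contact cannot be embedded and are written as NA.
The default k = 5 matches the usual cross-method comparison setting;
the gap statistic is available to choose k from the data. Cluster
labels are arbitrary under k-means, so clusters are canonically renamed
in decreasing order of a per-bin signal (accessibility, gene density —
the pipeline defaults to inter-chromosomal degree, which tracks open
chromatin); ties break toward the larger cluster, then the lower
original index.

## Exact objectives as oracles

O1 and O2 are also implemented by direct summation (O2 with a full,
max-subtracted softmax per node). These are far too slow for training
but exact, and the test suite uses them to verify that sampled SGD
actually lowers the true objectives on ≤50-node graphs, and that
single analytic updates match central finite differences to 1e-5
relative.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| resolution | 100 kb | bin size of the genome tiling |
| dim | 100 | embedding dimension per order |
| negative | 5 | noise nodes per positive update |
| samples | 25 (millions) | total edge draws |
| alpha | 0.5 | second-order weight in joint mode |
| initial_lr | 0.025 | SGD step, decaying linearly to 1% |
| k | 5 | number of sub-compartments |
| min_pet | 5 | ChIA-PET loop support threshold |

The learning-rate schedule, initialization (uniform ±0.5/d) and noise
exponent follow the common LINE/word2vec practice. With `workers=1`
and a fixed seed training is bit-reproducible; multi-worker training
is lock-free (hogwild) and only statistically, not bitwise,
reproducible.

## Evaluation

* **Silhouette** s_i = (b_i − a_i)/max(a_i, b_i) with Euclidean
  distances (scikit-learn's implementation; singleton clusters score 0).
* **Davies–Bouldin, all-pairs variant**: cluster dispersion d_i is the
  mean pairwise distance within cluster i and the separation d_ij the
  mean over all between-cluster pairs; DBI = (1/k) Σ_i max_j D_ij with
  D_ij = (d_i + d_j)/d_ij. This deliberately differs from the
  centroid-based classic and is hand-implemented.
* **Network topology** of each intra-sub-compartment subgraph:
  closeness (n−1)/Σ d(v,u) with Wasserman–Faust component scaling
  (subgraphs are often disconnected), betweenness Σ σ(s,t|u)/σ(s,t)
  (endpoints excluded, unnormalized by default), both via networkx;
  and the Barrat weighted clustering coefficient
  c_u = [1/(s_u(k_u−1))] Σ_(j,h) a_uj a_uh a_jh (w_uj + w_uh)/2 over
  ordered neighbor pairs (hand-implemented; networkx ships only the
  Onnela weighted variant). Shortest paths use hop counts by default,
  with an inverse-weight (1/w_ij) length option — whether contact
  weights should act as distances is genuinely open, so both modes are
  reported.
* **ChIA-PET**: intra-chromosomal loops with ≥ 5 PETs; an anchor gets
  the label covering strictly more than half of it (against the union
  of same-label bins), else NA; loops with an NA anchor are excluded
  from all counts. M counts (left label, right label); M_sym = M + Mᵀ;
  M_norm = M_sym / ΣM_sym. The intra/inter ratio is reported +∞ with a
  flag when no inter-compartment loop exists. Fisher's exact test
  (scipy, hypergeometric) compares two assignments' 2×2 intra/inter
  tables; Mann–Whitney (exact for n ≤ 8 without ties) compares
  per-node metric samples.
* **Functional**: per-compartment signal enrichment is the compartment
  median over the genome-wide median of coverage-weighted per-bin
  means; interval enrichment is the per-bin midpoint rate relative to
  genome-wide (midpoint attribution is a documented choice; an
  any-overlap rule would differ only for anchors spanning boundaries).
  The co-expression profile computes Spearman ρ across replicates for
  every same-chromosome TSS pair within a distance ceiling (ceilings
  step by 100 kb up to 10 Mb by default) and averages intra- and
  inter-compartment pairs separately. With ≤ 6 replicates p-values
  come from the exact permutation distribution of ρ.

### The significance filter caveat

Filtering pairs at p < 0.05 before averaging mirrors the published
procedure, but with 6 replicates the exact permutation p is coarse:
only |ρ| ≳ 0.83 passes, so the filter keeps near-perfect correlations
from *both* groups and collapses the intra/inter contrast toward 1.
The filter is therefore on by default but the unfiltered means are
always reported, and the simulation-based checks assert on the
unfiltered ratio.

## Synthetic data

The generators produce exactly the statistical structure the method
exploits, with ground truth:

* `simulate_hic` — planted partition: labels drawn independently per
  bin (so compartments span chromosomes, as real ones do); each
  inter-chromosomal pair draws Poisson(μ_in = 20) weight within a
  compartment, Poisson(μ_out = 2) between; zero weights omitted.
  Study scale is 6 chromosomes × 40 bins (240 bins), K = 5. Real Hi-C
  counts are overdispersed; a Negative-Binomial mode exists, but block
  structure, not dispersion, is what recovery depends on.
* `simulate_loops` — with probability p_intra = 0.8 both anchors land
  in same-label bins of one chromosome, else in different-label bins;
  anchors are 10 kb intervals centered in bins; PET counts are shifted
  geometric (mean 5).
* `simulate_signal` — per-bin value = effect[label] + N(0, 0.5),
  clipped at 0, one bedGraph interval per bin.
* `simulate_expression` — per gene and replicate:
  baseline + global[rep] + factor[label, rep] + noise. The global
  factor (sd 1.0) plays the role of a library-size effect common to
  all genes; without it both group means of ρ are ≈ 0 under the null
  and their ratio is undefined rather than ≈ 1. The compartment factor
  (sd 1.0 vs noise sd 0.5) is what makes intra pairs co-vary more.

What passing these tests does *not* show: robustness to Hi-C
normalization artifacts, distance-dependent intra-chromosomal
structure (out of scope by design), overdispersion beyond Poisson,
copy-number effects, or the cell-type mixtures of real nuclei. The
simulation demonstrates that the estimator recovers the structure it
assumes, at desk scale.

## Numerical choices

* Sigmoid arguments clipped at ±35; softmax rows use max subtraction.
* Alias tables built by Vose's method; stored probabilities sum to 1
  within 1e-12.
* Duplicate contact records are summed (tolerant of symmetric dumps);
  zero/negative/NaN weights dropped with a warning count.
* Gap statistic: references uniform in the PCA-aligned bounding box
  (rotation-invariant); W_k is k-means inertia; s_k includes the
  sqrt(1 + 1/B) correction. Default selection is Tibshirani's
  sequential rule; a `global-max` rule is offered because on
  high-dimensional embeddings the sequential rule can stop at k = 1
  when gap(1) ≈ gap(2) within reference noise even though the gap
  curve peaks sharply at the planted k.
* k-means inertia ties across restarts resolve to scikit-learn's
  first-best; seeds fix all of simulation, training and clustering.

## Problem sizes used in checks

Recovery runs use 240 bins / ~20k edges / 1M edge draws at dim 32;
objective-decrease checks use 30-node graphs where the exact softmax
is computable; metric-oracle equivalence uses ≤ 15-node graphs against
brute-force shortest-path and pairwise-distance oracles; correlation
profiles use 400 genes × 6 replicates with 400 kb steps to 4 Mb
(chromosomes are 4 Mb at this scale). These sizes were chosen so every
property is checked against an exact or well-conditioned reference.

## Known limitations

* The inter-chromosomal graph leaves bins without trans contacts
  unlabeled (NA) rather than imputing them.
* Separate-mode concatenation discards context vectors, so second-order
  probabilities cannot be re-evaluated on the combined embedding.
* The all-pairs Davies–Bouldin is O(n²) in memory per cluster pair;
  fine at bin counts up to ~10^4, not meant for base-pair resolutions.
* Exact Mann–Whitney enumeration is only used for tie-free samples of
  n ≤ 8; elsewhere the tie-corrected normal approximation applies.
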