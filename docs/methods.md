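# Methods

This note records the model assumptions, the numerical and design choices
made where the method description leaves room, and what the synthetic test
bed does and does not establish.

## Problem setting and assumptions

A labelled *source* domain and an unlabeled *target* domain observe the
same m activities. The method assumes: (i) the target's activity set is a
subset of the source's; (ii) the inter-activity structure — relative
prevalence, within-class density, and which activities border which in
feature space — is approximately preserved across domains even when the
feature spaces themselves are unrelated; (iii) each activity produces a
coherent cluster in its own domain's feature space. Under these
assumptions label transfer reduces to matching two small weighted graphs
instead of aligning two feature distributions.

## Pipeline and numerical choices

**Windowing and features.** Sliding windows of 2 s with 25% overlap
(stride = window·(1−overlap); half-open sample ranges; windows are counted
by floor((T−w)/stride)+1). Per channel, 16 time-domain statistics in a
fixed documented order; variance and standard deviation use the sample
(N−1) denominator, and skewness/kurtosis are defined as 0 on constant
windows to avoid NaN propagation into the graph stage. Two features need
conventions the plain formulas do not supply:

* *zero-crossing rate* is implemented literally as the fraction of
  exactly-zero samples; a conventional sign-change rate is available as a
  separately named optional feature, off by default.
* *entropy* is computed on p_i = (|s_i| + 1e−12)/Σ(|s_j| + 1e−12) with the
  natural log, which is finite on arbitrary real signals and coincides
  with −Σ s log s on non-negative normalised input.
* the *triaxial angle* is max_i arctan(z_i/√(x_i²+y_i²)), with the
  arctan limit ±π/2 when the horizontal norm vanishes.

A window's label is the majority per-sample label (ties to the
first-occurring label); unlabeled windows are dropped from labelled
matrices. UMAP reduction (fixed random_state, deterministic) is available
but is pass-through by default: the shipped synthetic features are already
low-dimensional, and reduction is a knob for high-dimensional real feature
CSVs.

**Network graph.** Mutual k-NN under cosine distance 1 − cos. Neighbour
ranking breaks ties by smaller vertex index, and a duplicate point
(distance 0) counts as a neighbour, so the construction is fully
deterministic. Default k = max(3, round(0.02·n)) — clustering quality is
best on sparse graphs around 2–5% of n.

**Core cluster identification.** CNM greedy modularity communities, then
greedy merging of the pair with maximal α = Cut/((Δ_i+Δ_j)/2) (ties to the
lexicographically smallest index pair; denominator floored at 1 when both
clusters are edgeless) until the number of source classes remains.
Statistics are updated incrementally and satisfy ΣΔ + ΣCut = |E| after
every merge. Two robustness rules matter in practice:

* *Noise shards.* Tiny connected components and tiny residual communities
  (< max(3, 1% of n) vertices) have α ≈ 0 to everything, can never be
  absorbed by merging, and would otherwise occupy core-cluster slots and
  force two genuine activity clusters to merge. They are set aside and
  labelled at the end by the nearest mapped-cluster centroid (cosine),
  flagged in the output, so every observation still receives exactly one
  label.
* *Too few communities.* Greedy modularity can return fewer communities
  than classes (merging can never split); the pipeline then rebuilds the
  graph with k halved — sparser graphs yield more communities.

**Dependency statistics on a densified graph.** Clustering and the
structural fingerprint have opposite sparsity needs. On a 2% graph the cut
table of a well-clustered partition is nearly empty: the edge tier of the
mapping then has nothing to match and degenerates into tie-breaking noise.
The pipeline therefore keeps the sparse graph for community detection but
recomputes Δ, σ and Cut on a denser graph — k doubled until the target
dependency graph carries at least 2m nonzero edge weights (capped at
0.2·n), the source using the same densified k so both domains' weights
share a scale. Both thresholds are configuration keys.

**Mapping.** All three bipartite solves use `scipy`'s Hungarian
implementation on zero-padded square matrices with an added refinement:
among equal-cost optima the lexicographically smallest assignment vector
is selected (forced-assignment re-solves; ties compared at 1e−9). Dummy
matches are excluded from votes and reported costs. Vote accumulation —
the one genuinely open design point — is: a vertex match (i→j) votes once
for (i, j); an edge match (a,b)→(c,d) votes for (a,c) and (b,d),
respecting direction; and a match in which **either matched weight is
zero abstains**. A zero weight is an absent relationship; its matches are
forced or tie-broken rather than structural, and counting them floods the
vote table with an index-order artifact that can outvote the informative
matches. Mappings constructed without weight annotations vote
unconditionally, so the rule is confined to one function and alternative
rules can be tested against it. If no votes exist at all (fully degenerate
weights) the pipeline falls back to the vertex tier.

## Synthetic domain pairs

The generator stands in for multi-device activity datasets. m class
archetypes are drawn once in a shared latent space (d_latent = 8) and
scaled so the mean inter-archetype distance equals `separation` times the
mean within-class RMS deviation; separation 4 with observation noise 0.3
is the reference condition. Three latent properties are shared between
domains because they are properties of the *activities*:

* the archetypes (inter-class geometry),
* per-class covariance: unit variance in an intrinsic subspace whose
  dimension is log-spaced from 1 to d_latent across classes (variance
  floor 0.25 elsewhere) — static postures are low-dimensional, locomotion
  fills the space, and this is precisely the density signature Δ/σ
  measures,
* class proportions, geometrically decaying with ratio 0.75 (imbalanced,
  as real activity data is; sizes feed the w_e denominators).

Each domain then applies its own observation map — identity, rotation,
random linear, channel drop, or rotation+drop — at its own gain, plus
isotropic observation noise. Class counts use deterministic allocation
(round(p·n), remainder to the largest class) so fixtures are exact;
multinomial sampling is a flag. Three named scenarios mirror the standard
transfer settings: `cross_modality` (two different random-linear maps,
d_obs = 12 — equal dimensionality so that a no-transfer classifier can be
run at all), `cross_location` (rotation vs. rotation+channel-drop to 6
channels), `cross_subject` (identity maps, higher noise and gain in the
target). A raw time-series generator (per-class sinusoid signatures +
drift + noise) exercises the windowing/feature path end to end.

What passing on this test bed shows: the pipeline recovers planted
structure when the structural-preservation assumption holds, exactly
degrades as overlap grows, and beats a no-transfer classifier by a wide
margin under feature-space shifts. What it does not show: robustness to
violated assumptions (activities missing from the source, non-stationary
wearers, sensor drift), to temporal autocorrelation between windows, or to
the idiosyncratic noise of real hardware.

## Problem sizes and evaluation

The reference experiments run m = 5 classes with n = 1000 windows per
domain; the acceptance script uses 10 generation seeds for the
cross-modality condition and reports medians. Metrics follow fixed
conventions: NMI with base-2 entropies and 2I/(H+H) normalisation
(defined as 1 when both labelings are single-class), purity as
majority-mass over N, labeling accuracy as the macro one-vs-rest
(TP+TN)/n average over true classes, and F1 as the harmonic mean of macro
precision and macro recall (the mean-of-per-class-F1 variant is behind a
flag; zero-denominator classes contribute 0).

## Known limitations

* The consensus is only as good as the dependency weights; domains whose
  class structure is genuinely symmetric (equal sizes, equal densities,
  uniform overlaps) give the mapping nothing to grip, and a swapped
  cluster pair costs ~0.2 labeling accuracy at m = 5.
* The source dependency graph uses label classes (not CCI), so its cut
  magnitudes are systematically larger than the target's on very clean
  data; the densified statistics reduce but do not remove this asymmetry.
* One-to-one mapping only: an activity absent from the source ends up
  absorbed into whichever class its cluster maps to (or flagged fallback).
* Pure-Python greedy modularity dominates runtime beyond a few thousand
  windows per domain; the O(n²) affinity matrix dominates memory beyond
  ~20k windows.
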