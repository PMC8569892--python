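# Methods

This note documents the models, conventions and design choices behind
`thermonet`, in the order the pipeline runs.

## Study design and preprocessing

The pipeline assumes a paired design: a set of lakes, each contributing
one sediment and one water sample, with an OTU count table normalised
(rarefied) to a common depth. Rarefaction subsamples without
replacement (multivariate hypergeometric draw), drops samples below the
target depth with a warning, and is deterministic under a seed. After
rarefaction every relative abundance is an integer multiple of
1/depth, so the 0.01% abundance threshold corresponds to ≥ 3 reads at a
depth of 27,890.

Two retention filters feed network construction:

- **Metacommunity filter** — an OTU is retained iff it is nonzero in
  *both* the sediment and the water sample of the same lake for at
  least `min_lakes` (default 8) lakes, *and* its habitat-wise mean
  relative abundance exceeds `min_ra` (default 10⁻⁴) in sediment or in
  water. "Abundance in either habitat" is read as the habitat-wise
  mean, parallel to the per-habitat filter; a per-sample-maximum
  reading would make the metacommunity filter laxer than the habitat
  one. Both readings are available through the same threshold
  parameter, and the conjunction of presence and abundance conditions
  is order-independent.
- **Habitat filter** — nonzero in ≥ `min_lakes` samples of that
  habitat and habitat-wise mean relative abundance strictly above
  `min_ra`.

Presence means a nonzero count after rarefaction; no pseudo-count
threshold is applied. Lake counts use ≥, abundance thresholds are
strict (>).

**Habitat enrichment** is operationalised as a two-sided Wilcoxon
rank-sum (Mann–Whitney U) test of relative abundance between the two
habitats' samples, BH-adjusted across OTUs; an OTU is labelled with the
habitat of higher median abundance when adjusted P < α (default 0.05).
The exact criterion differs between published studies; this choice is a
configurable operationalisation and is recorded with each output.
Exact small-sample P-values are used when the data are tie-free.

## Co-occurrence networks

All retained OTU pairs are screened with Spearman's rank correlation
(average ranks for ties; two-sided P from the t-distribution
approximation — verified to match `scipy.stats.spearmanr`, but computed
via a single rank-matrix product for all-pairs speed). Zero-variance
profiles have undefined correlations and never become edge candidates.
P-values are Benjamini–Hochberg adjusted; the BH family is every pair
with a defined correlation in one network build. Edges require
|R| > 0.80 *and* adjusted P < 0.01, both strict; isolated nodes are
then removed. The significance threshold is configurable because
published workflows vary between 0.01 and 0.05; 0.01 is the default.

The metacommunity network correlates across all samples of both
habitats jointly (metacommunity OTUs are defined by joint presence);
each habitat network uses only its habitat's samples. Both choices are
recorded in the network's provenance metadata.

## Topology panel

For one network the panel comprises node and edge counts, average
degree (2m/n exactly), average shortest-path length over connected
pairs, diameter (largest finite shortest-path distance), mean local
clustering, Freeman degree and betweenness centralization, and the
modularity of the detected partition. Conventions, all recorded in the
summary object:

- Disconnected graphs average path length over finite pairs only; this
  is required for Erdős–Rényi replicates, which can be disconnected.
- Local clustering of degree-0/1 nodes contributes 0 to the mean
  (configurable to exclude those nodes).
- Centralizations are normalised by the star-graph maximum: degree by
  (n−1)(n−2), betweenness by (n−1)²(n−2)/2 with raw unordered-pair
  betweenness. Betweenness centralization is invariant to the
  ordered/unordered pair-counting convention because numerator and
  normaliser scale together, so no separate convention flag is needed;
  the reproduction of the published random-ensemble value (0.036 at
  n=128, m=471) confirms the star normalisation matches the original
  toolchain.

The panel has a fast array core (scipy C BFS for distances, dense
triangle counting for clustering, igraph's C betweenness) so that
999-replicate null ensembles at n ≈ 1000 stay in the minutes range on
one CPU.

## Erdős–Rényi null model

G(n, m): m edges drawn uniformly without replacement from the C(n, 2)
possible pairs — fixed edge *count*, matching "same number of nodes and
edges", not fixed edge probability. Each replicate's panel is
summarised as mean ± SD; observed metrics are scored with
Z = (obs − mean)/SD and a two-sided standard-normal P (the conventional
reference for this Z-test). A degenerate ensemble (SD = 0) yields
P = 1 when the observation equals the mean and P = 0 otherwise, and is
flagged. Modularity of each replicate uses the same detection algorithm
as the observed network. The default replicate count is 999; at the
largest studied size (n=1049, m=20857) the per-replicate spread of the
panel metrics is ≤ 10⁻³, so 100–200 replicates estimate the ensemble
mean to well within the reporting precision, and the reproduction
script uses 150 there.

## Modules and node roles

Module detection maximises Newman–Girvan modularity
Q = Σ_s (e_ss − a_s²). The default algorithm is greedy CNM
agglomeration, which is deterministic; Louvain is available behind a
method flag with an explicit seed. Modules are labelled A, B, C… by
decreasing size. Major modules have strictly more than 10 nodes
(`min_size=11`). Reported Q always equals a recomputation from the
returned partition (tested to 10⁻¹²).

Node roles use the within-module degree z-score
Zi = (k_is − mean_s)/sd_s and participation coefficient
Pi = 1 − Σ_t (k_it/k_i)², with the sum over *all* modules including
singletons and Zi/Pi computed on the full network. Degenerate cases are
flagged: modules with zero spread in within-degree give Zi = 0 for
their members; isolated nodes get Zi = Pi = 0. Thresholds Zi ≥ 2.5 and
Pi ≥ 0.62 (cut-inclusive on the hub side) split nodes into peripherals,
module hubs, connectors and network hubs.

## Environment–module–community path model

β-diversity is Bray–Curtis, BC(x, y) = Σ|x−y| / Σ(x+y), on relative
abundances over a module's OTUs (or all OTUs for the community); a
sample pair with no abundance in the subset has an undefined
dissimilarity (NaN). Environmental "variation" is operationalised as
the pairwise absolute difference of the z-standardised variable within
one habitat — a distance-based reading chosen because the responses
(β-diversities) are intrinsically pairwise; a per-lake formulation is
not expressible for them.

The path model is piecewise: one OLS fit per module
(module β ~ all environmental distances) and one for the community
(community β ~ all major-module βs), on z-standardised upper-triangle
vectors, so coefficients are standardized path coefficients and are
invariant to rescaling any input (tested to 10⁻¹⁰). Because pairwise
distances are not independent observations, OLS P-values are
anti-conservative; a Mantel-style permutation option
(`p_method="permutation"`, default 999 permutations of sample
identities of the response matrix, P with the +1 correction) provides
calibrated tests — its type-I error is verified at ≈ 5% on null data.
OLS remains the default for comparability with common piecewise-path
practice; the method used is recorded in the result. Collinear module
βs (condition number > 10⁸) trigger a warning but coefficients are
still reported. Only major modules enter the community layer.

## Synthetic communities

The generator emulates the paired-lake design: `n_lakes` (default 23)
lakes × 2 habitats, counts drawn per sample as one multinomial of
`depth` (default 27,890) reads, so row sums equal the rarefaction depth
exactly and identical configurations are bit-identical.

Structure is planted through a latent-factor copula. Environmental
variables (pH, conductivity, TN, TP) are standard normal per lake and
shared between a lake's two samples; organic carbon is drawn per
habitat (SOC in sediment, DOC in water). Each module j has a per-sample
driver L_j = Σ_v c_jv·env_v + ε with lake-level noise
ε ~ N(0, `driver_noise_sd`=0.3); the coefficients c_jv (default: one
variable per module at 0.6) are the ground-truth environment–module
paths. An OTU's expected abundance is

    baseline × exp(module_strength · L_j) × enrichment × gamma noise,

with log-normal baselines (σ=1.2, a realistically heavy-tailed
abundance distribution), `module_strength` ∈ [0, 1] scaling the shared
factor, a multiplicative `enrichment_fold` (default 8) on expected
relative abundance in the preferred habitat — multiplicative rather
than presence/absence, because enriched taxa must still occur in both
habitats to pass the joint-presence filter — and mean-1 gamma noise
with variance `noise_dispersion` (default 0.25). Habitat-pool OTUs
(background diversity) are down-weighted 50-fold outside their own
habitat but never absent. Co-abundance within a module is co-monotone
in the shared driver, hence detectable by Spearman correlation without
assuming any parametric marginal; at module_strength ≈ 0.9–0.95 with
small noise, within-module correlations exceed the 0.8 edge threshold
and the full pipeline recovers the planted partition with adjusted Rand
index > 0.9 (recovery is scored over the planted-module nodes in the
network, since background OTUs carry no planted partition to recover,
and is empirically non-decreasing in module strength).

What the generator does *not* emulate: compositional closure artefacts
beyond the multinomial itself, phylogenetic correlation among OTUs,
spatial autocorrelation among lakes, overdispersed sequencing error, or
taxonomy beyond arbitrary labels. Passing recovery tests therefore
demonstrates the pipeline's correctness on data satisfying its own
assumptions, not performance guarantees on field data.

## Problem sizes and determinism

The test and reproduction workloads use 999-replicate null ensembles at
(n=128, m=471) and (n=607, m=2265) and 150 replicates at (n=1049,
m=20857), synthetic communities of 300–400 OTUs at full 27,890-read
depth, 10-seed path-recovery panels, and 200-dataset calibration runs —
sizes chosen so the whole suite completes in minutes on a single CPU
while keeping Monte-Carlo error far below the tolerances being checked.
All randomness flows through explicit integer seeds (numpy Generator);
the pipeline is bit-reproducible from its manifest.

## Known limitations

- Spearman on relative abundances ignores compositional coupling; the
  negative-correlation bias of closure is inherited from the original
  design (compositionality-aware estimators are out of scope).
- Greedy CNM detection is deterministic but not optimal; module counts
  on real data are algorithm-dependent.
- The OLS path-model P-values ignore pairwise dependence (use the
  permutation option when calibration matters).
- The enrichment test assumes exchangeable samples across lakes; a
  paired or mixed-model formulation could gain power.
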