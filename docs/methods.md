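# Methods

## The homology network and duplicability K

All-against-all similarity records (BLAST tabular dialect; only query
id, subject id and E-value are consumed) are thresholded at E ≤ 10⁻³⁰
and merged into an undirected simple graph. Self-hits are dropped — a
gene is not its own duplicate — and reciprocal hits are merged keeping
the smaller E-value (strongest evidence, symmetric in input order).
The threshold comparison is inclusive by default; exactly-boundary
edges are the only ones affected, and an `inclusive=False` switch is
exposed. K counts distinct adjacent genes, not HSPs: a subject
appearing in several local alignments contributes once.

Edge weights are W = min(−log₁₀E, 300) / M, where M is the maximum
capped −log₁₀E over the edges of the edge's connected component
("cluster"). The cap handles E-values reported as exact zeros (300
exceeds any double-precision exponent). Normalizing by the maximum
−log₁₀E, rather than the maximum E, is the only reading that puts W in
(0, 1] with the strongest edge of each cluster at exactly 1; the
normalization scope (per component vs whole network) is a config flag
(`weight_scope`).

## Power-law fitting

P(K) histograms use raw integer K bins over genes with K ≥ 1;
zero-count bins are omitted (their log is undefined). Fits are
unweighted ordinary least squares of log₁₀P(K) on log₁₀K, with
α = −slope; base-10 throughout (the slope is base-invariant). Counts
and percentages give identical α, so both are accepted. Curve
comparison helpers: `overlay_shift` rescales one curve so its leftmost
point coincides with a reference (a vertical translation in log space,
slope-preserving), and `restrict_to_k_values` cuts a background curve
to a focal group's K support so the two are point-for-point comparable.
A constant P(K) is treated as a perfect flat-line fit (slope 0,
R² = 1), avoiding a 0/0.

## Genetic interaction classes

Annotation strings are case-folded and matched against two fixed
vocabularies: GA = {synthetic rescue, phenotypic suppression},
GC = {synthetic lethality, phenotypic enhancement}. Other strings (e.g.
"dosage rescue") stay UNCLASSIFIED rather than being guessed. A pair
annotated on both sides is CONFLICT and excluded from GA/GC analyses
(the count is logged). Only pairs that are homology-network edges —
actual duplicate pairs — are classified. Two per-group K views exist:
*members* (K of the distinct genes in the group's pairs) and
*co-occurrence* (K of every third gene whose hit list encloses both
members of a pair; since there are no self-edges a pair member can
never enclose itself).

## PPI distances

Distances follow the node-count convention: path length = number of
proteins on the path, endpoints included (2 = direct interaction).
Breadth-first search computes this on the unweighted interaction graph
(depth-first traversal does not return shortest paths, so BFS is the
algorithm that computes the quantity defined). Unreachable pairs are
never assigned a pseudo-distance; they are tallied and excluded from
percentages and means, with counts in the run log. Control pairs are
sampled uniformly from all node pairs not in the duplicate-pair set,
without degree matching, and are kept (not resampled) if unreachable.

Distribution comparisons use Pearson's chi-square on raw counts, no
continuity correction (a `correction` flag exists). With a boundary
(default 3.5) counts collapse to (≤ boundary, > boundary) in a 2×2
table; without one, a k×2 table over the union of observed distances is
used, pooling sparse tail (then head) cells until expected counts reach
5 — the pooling rule is a documented default, not configurable per
test. Family-level distance is the mean over all pairwise distances
among {gene} ∪ homology-neighbors present and mutually reachable in the
PPI graph; genes are binned by floor(K / bin size) (default bin size 1)
and the Pearson correlation is taken between bin midpoints and bin mean
distances. Two-bin summaries get r = ±1 by definition with no p-value.

## WGD vs SSD and the resampling null

A duplicate pair is WGD iff it appears in the synteny-derived pair
list; all other duplicate pairs are SSD, so the two classes partition
the duplicate pairs. Listed pairs without a retained homology edge are
dropped and counted. The contingency summary reports per class the pair
count, GC and GA counts, percentages and the GC/GA ratio, rounded to
one decimal for display; a class with no GA pairs has an undefined
ratio (reported as NA/None, never 0).

The resampling null locates a small focal group (by default the GA∩WGD
pairs) against `reps` = 100 random same-size subsets of the WGD pairs,
drawn without replacement within a subset. Two p-values are reported:
the add-one empirical estimator (#{null ≥ observed} + 1)/(reps + 1),
which cannot return 0 at finite reps, and a normal upper-tail p from
the z-score of the observed mean against the null mean and SD. At 100
reps the empirical estimator's granularity is 1/101, which is why the
smoother normal-tail value is emitted alongside it.

## Weighted clustering coefficient

The Barrat arithmetic-mean form is the default:
Cᵢ = [1/(sᵢ(Kᵢ−1))] Σ over adjacent unordered neighbor pairs (j, k) of
(Wᵢⱼ + Wᵢₖ), with strength sᵢ = Σⱼ Wᵢⱼ. It is defined only for K ≥ 2,
reduces to the unweighted clustering coefficient at unit weights, and
lies in [0, 1]. The geometric-mean (Onnela) form is available behind
`weight_scheme="onnela"` so the choice of weighting is auditable; the
robust claim is the *sign* of the C–K correlation, which does not
depend on the variant. For the K-binned log-log analysis (default bin
size 2), bins with mean C = 0 cannot enter the log-log correlation and
are excluded with a logged count.

## The synthetic proteome

The generator emulates the statistical structure the analysis assumes,
not any real genome:

- **Families.** Sizes s ≥ 2 are drawn by inverse CDF from the
  size-debiased law P(s) ∝ (s−1)⁻ᵅ/s, truncated at `max_family_size`,
  so that the *gene-level* duplicate-count distribution follows K⁻ᵅ
  (each family of size s contributes s genes at K = s−1; without the
  1/s debias the gene-level law would be one power shallower than the
  family-level one). Within a family the homology relation is a
  complete graph. Leftover genes remain singletons.
- **`max_family_size` = 12 (default).** A complete family of size s
  puts at least s genes at K = s−1 wherever it occurs, so an observed
  P(K) point can never lie below the count = K+1 line; beyond the K
  where the target law crosses that floor (K ≈ 10 at n = 5000,
  α = 2.5) the per-K unweighted log-log fit is structurally flattened
  no matter how sizes are sampled. The default keeps the family-size
  support inside the identifiable range of the estimator.
- **E-values.** −log₁₀E per pair ~ Normal(150 − slope·(s−2), 15),
  clipped to [30, 300]: mean divergence grows with family size at rate
  `evalue_divergence_slope` (default 6 per extra member), and the floor
  at 30 guarantees every within-family pair passes the 10⁻³⁰ retention
  threshold. Values are written with 3 significant digits in scientific
  notation and round-trip through the BLAST tabular reader.
- **Edge dropout** (`edge_dropout_slope`, default 0): a within-family
  pair in a family of size s is omitted with probability
  1 − exp(−slope·(s−2)). Size-2 families are never broken. Dropout
  makes large families incomplete — which is what drives C below 1 and
  gives the C–K relationship its slope — but it also distorts the
  K = s−1 identity, so it is off by default and enabled (0.05) in the
  analysis bundle configs.
- **PPI graph.** Random-attachment growth over a shuffled gene order
  (each new node links to 2 placed nodes; connectedness by
  construction). If a new node's family already has placed members, one
  link is redirected to a random placed family member with probability
  q(s) = (1 − e^(−λ))·e^(−λ(s−2)/4), λ = `ppi_distance_slope`
  (default 1.2). λ = 0 disables the coupling entirely (paralogs placed
  like any other node); λ > 0 puts small families adjacent and lets
  large families drift toward the background distance, so expected
  within-family distance increases with family size. The decay scale 4
  is a fixed shape constant.
- **Genetic annotations.** Every retained within-family pair is
  annotated: "synthetic rescue" with probability expit(λ_GA·z), where z
  is the pair's standardized *inverted* −log₁₀E (higher divergence →
  more antagonism) and λ_GA = `ga_logistic_slope` (default 3);
  otherwise "synthetic lethality". Slope 0 degenerates to a fair coin,
  so the overall GA fraction at default settings is near 50% — the
  logistic link is a stand-in whose intercept and slope are *not*
  calibrated to yeast, where GA is roughly an order of magnitude rarer.
  Only the direction of the divergence–antagonism coupling is asserted.
- **WGD list.** `wgd_fraction` (default 0.12, roughly the yeast
  465/4227 proportion) of the within-family pairs, chosen greedily in
  ascending E-value order (least diverged first) under the constraint
  that no gene appears twice; at fraction 1 this yields a maximal
  matching.

All four generators draw from independent child streams
(`numpy.random.SeedSequence(seed, spawn_key=(stage,))`) of the one
config seed, so each is individually and jointly deterministic. The
pipeline fans per-stage seeds (control sampling, resampling) out of the
root seed the same way.

What the generator does **not** emulate: actual sequences or
alignments (only pairwise E-values), between-family homology, hubs and
degree assortativity of real interactomes, annotation sparsity (every
duplicate pair is annotated, whereas SGD covers a small subset), and
realistic GA/GC base rates. Passing tests therefore demonstrate that
the pipeline recovers planted structure of these kinds, not that the
biological effect sizes are reproduced.

## Problem sizes and verification

The package's checks use: ten synthetic proteomes of 5,000 genes for
exponent recovery (10-seed mean within ±0.3 of the target 2.5); one
3,000-gene bundle with all couplings positive for the directional
recovery of the three evidence lines; 200 resampling draws × 100 reps
and 1,000 independence tables (n = 400) for calibration of the
empirical-p and chi-square utilities (rejection at 0.05 expected in
[0.01, 0.12] and [0.03, 0.07] respectively); and two 1,500-gene
end-to-end runs for byte-level determinism. These sizes were chosen as
the smallest at which the planted effects are comfortably identifiable;
`scripts/acceptance.py` recomputes all of them from scratch in a few
seconds.

## Known limitations

- The weighted-clustering variant in the source analysis is cited, not
  spelled out; if a different variant was used there, absolute C values
  differ (the sign of the C–K correlation is the robust claim).
- "Cluster" for weight normalization is taken as the connected
  component of the thresholded network — the only network-native
  grouping available; the `weight_scope` flag makes it auditable.
- The per-K unweighted log-log fit is a biased estimator of the
  exponent in small samples with heavy tails (see `max_family_size`
  above); maximum-likelihood power-law estimation is deliberately out
  of scope.
- Interaction networks are unweighted and undirected; no
  confidence-score filtering is applied.
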