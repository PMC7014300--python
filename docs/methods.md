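# Methods

## Ranked Correlated Sets

The pipeline's core object is the Ranked Correlated Set: a seed protein
plus the `target_size − 1` neighbors with the highest STRING combined
score in a pre-filtered interaction network. Two rules govern
construction:

* **Strict score filter.** An edge survives only if its combined score is
  strictly greater than `score_threshold` (default 700, STRING's
  conventional high-confidence cut). Scores are integers in [0, 1000];
  symmetric duplicate rows in the input collapse to one undirected edge
  keeping the maximum score, which makes the reader robust to files that
  list either one or both orientations with inconsistent scores.
* **Minimum-interactor discard.** A seed with fewer than `min_neighbors`
  (default 10) eligible neighbors is discarded rather than tested: a
  too-small foreground makes over-representation p-values incomparable
  across seeds. Seeds with between `min_neighbors` and `target_size − 2`
  neighbors are retained undersized (seed + all neighbors) and flagged;
  this reconciles the fixed-size goal with the minimum rule, which are
  otherwise contradictory for intermediate degrees. `target_size`
  (default 15) counts the seed itself.

Equal-score neighbors are ordered lexicographically by identifier. This
tie-break is arbitrary but deterministic, so set membership is identical
across runs and platforms; with integer scores in [0, 1000] ties at the
rank-15 boundary do occur in real STRING files.

## Over-representation analysis

For each (RCS, collection) pair the foreground is the RCS members
(including the seed — it is a member by definition) intersected with the
collection universe, and the universe is all genes appearing in the
size-filtered collection. This mirrors the default of standard enrichment
tools when no custom background is supplied; a caller can intersect
collections with a measured universe before testing if one exists. The
per-term statistic is the exact hypergeometric upper tail
P(X ≥ k | N, K, n), computed via `scipy.stats.hypergeom.sf` (log-gamma
based; verified against exact rational enumeration for all configurations
with N ≤ 25).

Decisions that shape the multiple-testing burden:

* Terms are size-filtered **before** testing (defaults 10–2000; the upper
  bound drops uninformative umbrella terms, the lower bound drops terms
  too small to ever reach significance against a 15-member foreground).
* Terms with k = 0 are not tested and do not enter the BH adjustment.
* BH runs per (RCS, collection) block — each RCS is characterized
  independently, and collections are separate hypothesis families.
* The q-value is the BH-adjusted p-value. (Some enrichment tools report a
  Storey q-value alongside; BH is used here because it is deterministic
  and assumption-free. With both cutoffs at 0.05 the BH q is the binding
  constraint in practice.)
* A term is significant iff p ≤ `p_cut` **and** q ≤ `q_cut` (defaults
  0.05/0.05).

Aggregation keys on (collection, term) and counts distinct supporting
seeds; a term enriched twice for the same seed (e.g. in re-runs or
overlapping catalogs) counts once. The bipartite term–seed incidence
matrix and its edge-list export support downstream network visualization;
layout/rendering is out of scope.

## Spectral-count correlation

Raw spectral counts are proxies for abundance confounded by per-sample
depth, so each count (plus a pseudocount) is divided by its sample's
pseudocounted total and log2-transformed. The pseudocount (default 0.5)
exists only to make zeros loggable; Spearman correlation is invariant to
any monotone per-sample transformation, so the correlation results are
insensitive to its exact value.

`spearman` computes rho as the Pearson correlation of mid-ranks (exact
under ties). The p-value uses the exact permutation distribution — all n!
orderings enumerated — for n < 10 when the data are untied, and the
classical t-approximation with n − 2 degrees of freedom otherwise. The
switch at n = 10 mirrors common statistical software: enumeration is exact
and cheap below it, and the t-approximation is accurate above it. Ties at
small n fall back to the t-approximation. Constant vectors yield an
undefined rho and are flagged (NaN record), not raised, so one degenerate
protein does not abort a correlation scan. No multiple-testing correction
is applied to correlation p-values by default, matching the plain
p ≤ 0.05 reporting convention of this analysis type.

## 2-DE spot testing

Per gel, spot volumes are background-subtracted (floored at zero — a
volume below background is noise, not signal), then divided by the total
corrected volume over **valid** spots of that gel; invalid spots are
excluded from the denominator and emitted as missing. Each spot is then
compared between the two replicate groups with a two-sided
pooled-variance Student t-test (the classical choice for triplicate gels;
Welch would be underpowered at n = 3 and the equal-variance assumption is
reasonable for technical replicates), significant at p ≤ `alpha`
(default 0.05), uncorrected. Spots lacking two non-missing values in
either group are reported untestable rather than raising.

## Synthetic data

The generator module emulates each input just closely enough that every
pipeline stage is exercised with known truth:

* **Network** — each seed owns a dedicated module of high-confidence
  neighbors (scores uniform in (700, 1000]); background edges default to
  scores ≤ 700 so planted neighborhoods are exactly the post-filter
  neighborhoods, and the score range is configurable to straddle the
  threshold when reader robustness is the point. Files carry `9606.`
  taxon prefixes and both edge orientations deliberately.
* **Gene sets** — one planted term per module (module ∪ seed plus 15
  filler genes), null terms with log-uniform sizes, and a guaranteed
  >2000-gene term so the size filter has work.
* **Counts** — negative-binomial marginals (default dispersion 0.3,
  typical of spectral-count overdispersion) around depth-scaled
  abundances, with per-sample depths log-range 20–60k so totals are
  unequal and normalization matters. Protein weights span ~3.5 decades,
  so low-abundance proteins produce zeros and exercise the pseudocount
  path. Planted rank correlations use a Gaussian copula (NORTA): counts
  are NB quantiles of correlated normal CDFs, with the latent Pearson
  correlation set to 2·sin(π·rho_s/6) so the population Spearman equals
  the target. Planted proteins are assigned high abundances: rank
  correlations at the low-count end are attenuated by discreteness, which
  is a property of count data, not of the estimator. The default 95
  samples matches the size of the tumor cohort this analysis type is run
  on.
* **Spots** — log-normal volumes (default CV 0.2) in two groups of
  triplicate gels, planted spots shifted by a fold change (default 4) in
  one group, per-gel additive background. Planted spots are drawn from
  the lower-abundance half of the volume range: because normalization
  divides by per-gel totals, fold changes on dominant spots would induce
  compositional shifts in every unchanged spot, which the generator
  avoids by construction (real 2-DE experiments change a negligible
  fraction of total volume).

One integer seed determines everything; each generator draws from its own
`SeedSequence(seed, spawn_key=(stream,))` stream so generators can re-run
independently.

What the generator does **not** emulate: STRING's evidence-channel score
calibration, annotation redundancy and the GO DAG structure, batch
effects or tumor purity in the count matrix, and spatial artifacts of gel
images. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated models, not robustness to every
pathology of real data.

## Calibration checks and simulation sizes

The acceptance checks (`tests/test_acceptance.py`,
`scripts/acceptance.py`) use these problem sizes, chosen to estimate each
quantity with standard error well inside its tolerance:

* hypergeometric oracle: every valid (k, n, K, N) with N ≤ 25 (44,225
  configurations) against exact integer enumeration, tolerance 1e-12;
* Spearman exact p: all-permutation oracle for n = 4…7;
* null calibration: 2,000 uniform 15-member foregrounds in a 1,000-gene
  universe against terms of sizes 20–400;
* planted recovery: 40 generated networks × 6 modules (240 module-terms);
  500 replicate count matrices at n = 95 for rank-correlation levels
  {0, 0.3, 0.6, 0.9}; 300 planted 4-fold spots across 30 tables.

One calibration subtlety: the hypergeometric tail with a 15-member
foreground is a **discrete** test, so its attainable size at nominal 0.05
is P(p ≤ 0.05) = P(X ≥ k*), where k* is the smallest overlap whose tail
falls at or below 0.05 — strictly less than 0.05 and dependent on the term
size (e.g. ≈0.037 for K = 50, ≈0.011 for K = 400 at N = 1000). Empirical
type-I rates are therefore checked against this exact attainable level
(within 3 binomial standard errors), plus a validity bound that no term
exceeds 0.05; demanding the empirical rate equal 0.05 itself would be
wrong for any correct implementation of a discrete test.

## Pipeline determinism

All orderings are explicit (score-then-lexicographic neighbor ranking,
q-then-p-then-term significance ordering, frequency-then-term
aggregation), floats are rendered with a fixed `%.10g` format, and the
manifest contains no timestamps, so identical config + seed reproduces
byte-identical outputs — verified as an end-to-end test. The manifest
records input SHA-256 checksums, the effective parameter set, per-stage
row counts and the discard report; failures mark the manifest FAILED with
the failing stage named, retaining any outputs already written.

## Known limitations

* Gene sets are consumed flat; no GO ancestor propagation or semantic
  de-duplication of related terms (enriched-term lists are redundant to
  the extent the collection is).
* The universe default (all collection genes) can be anticonservative if
  the experiment could only ever have detected a subset of it; supply an
  intersected collection when a measured universe exists.
* The narrative grouping of related enriched keywords into themes is
  interpretive and not reproduced algorithmically.
* Identifier mapping between STRING IDs and gene symbols is consumed as a
  user-supplied two-column table; no alias resolution is attempted.
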