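# Methods

## The screen model

`svscreen` analyzes pooled loss-of-function screens in which a guide
library is propagated under a selective pressure and the readout is the
change in guide abundance between treated and control populations. The
analysis makes no attempt to model growth mechanistically; it is a
rank/enrichment procedure on compositional count data:

1. **Filtering.** Guides with zero reads in *any* control sample are
   removed first — a zero control denominator makes the guide's ratio
   unstable in at least one replicate, so the strict any-replicate rule
   is used rather than zero-after-averaging. Genes left with fewer than
   4 guides are then dropped entirely ("over 3" guides are required for
   the gene-level statistics to be meaningful).
2. **Normalization.** Reads per million per sample. This removes
   sequencing depth exactly: multiplying any one sample's counts by a
   constant leaves every downstream number unchanged (a tested
   invariant).
3. **Replicate averaging.** Arithmetic mean of RPM values within each
   (condition, dose, timepoint).
4. **Log ratios.** Per guide and treated condition,
   `log2((treated + c)/(control + c))` with pseudocount `c = 0.5` RPM on
   both sides. The control column is timepoint-matched when the control
   condition was harvested at the same time, otherwise the single
   control column is used. Filtering guarantees control values > 0; the
   pseudocount only protects treated zeros, and at typical abundances
   (RPM ≫ 1) it perturbs ratios negligibly.
5. **Gene logFC.** Each guide's logFC is the mean of its ratios across
   the treated conditions; the gene's logFC is the mean over its guides.
   Because the ratio table is rectangular this equals the flat mean over
   all guide × condition entries.
6. **Significance.** Two-sample Kolmogorov–Smirnov test of the gene's
   per-guide logFC values (n = number of surviving guides) against the
   per-guide logFCs of *all* guides, the tested gene's own guides
   included. The statistic is the sup ECDF gap with ties resolved by
   evaluating at every pooled point; the p-value is the asymptotic
   two-sided one, clamped into (0, 1].

   The KS sample is deliberately the per-guide logFC, not the pool of
   per-condition ratios. The per-condition ratios of one guide share a
   control denominator (and, across doses, the same timepoint-matched
   control column), so pooling them yields a sample with within-guide
   correlation; treating those 4·n values as independent makes the test
   anticonservative — in a fully neutral simulation (1000 genes × 5
   guides, depth 10⁶) the pooled variant rejects at ~9% instead of 5%
   at the 0.05 level, while the per-guide variant is calibrated (~5%,
   KS distance of the p-value distribution from uniform ≈ 0.02). Guide
   logFCs are independent across guides, which is what the test
   assumes. A residual approximation remains: the asymptotic p-value at
   n = 5 guides and the gene's membership in its own background make
   the test very mildly anticonservative (null rejection ≈ 0.05–0.065
   across seeds), which BH absorbs comfortably.
7. **Multiplicity and hits.** Benjamini–Hochberg across all genes
   passing filters (no method is canonical for this design; BH is the
   field default). A hit requires strictly `logFC > 0` and
   `FDR < alpha` (default 0.05).

The object surface follows the statsmodels convention: a `ScreenModel`
holds the data and options, `fit()` runs steps 1–7 and returns a
`ScreenResults` with the gene table, intermediates, filter report and a
text `summary()`.

## Cross-screen relative score

Both screens' genes are ranked by logFC (rank 1 = highest; ties receive
average positional ranks) and each gene present in both gets
`relative_score = rank_control / rank_treated`. Exchanging the screens
maps every score to its reciprocal. "Expressed" is operationalized as
present in both result tables — the package has no independent
expression data, so its universe is what its inputs contain. The
set-level test is upper-tail hypergeometric: population = all shared
genes, successes = those with score strictly > 1 (a tie at exactly 1
counts as not-above), draws = the set's shared members. Members with
score > 100 are reported as strongly treatment-specific. The
hypergeometric tail is computed by exact log-space summation of the PMF
(gammaln + logsumexp), and is cross-checked in the tests against both
integer-exact enumeration and an independent library implementation.

## Over-representation analyses

`top_n_enrichment` selects the top N genes by logFC (N = 30 by default,
matching the common "top hits" figure convention; ties broken by gene
name for determinism) and tests each gene set hypergeometrically with
the *analyzed* genes as universe — only genes that survived filtering
could have been selected, so using the whole genome would inflate
significance. BH is applied across sets. `direction_set_test` consumes
an externally produced differential-expression table (the package never
fits DE models) and tests whether a set's members are over-represented
among genes labeled `up`; population, successes and draws are all taken
from the table, and both are exposed as explicit inputs because no
single convention exists. `normalize_viability` divides plate-reader
readings by the mean of the no-treatment control wells.

## The simulator

The generator emulates the *structure* of a two-dose, two-timepoint
drug screen with a vehicle control, not its biology. Per gene a class is
drawn: neutral (effect 0), essential (effect `essential_effect` ≤ 0 in
every condition), or synthetic-viable (additional `sv_effect_treated` ≥
0 in treated conditions only). Effects are log2 changes in expected
guide abundance per unit screen time: sample proportions are
`p_i ∝ baseline_i · 2^(effect·t)`, renormalized, so a ground-truth
effect lands on the pipeline's logFC scale directly, minus a
compositional shift of order the spiked mass fraction. Baseline guide
abundances are log-normal(0, `baseline_dispersion`). Counts are
multinomial at fixed `depth`; with `overdispersion = φ > 0` the
proportions are first multiplied by gamma(shape 1/φ, mean 1) noise,
which adds a single biological-noise knob while keeping exact column
sums. One seed drives everything; each sample draws from a substream
keyed by a CRC32 of its name, so counts are reproducible per sample
even if the sample list changes.

Defaults are desk-scale choices, stated here once: 5 guides/gene (the
real genome-wide libraries use 4–6), depth 10⁶ reads/sample (10×
coverage of a 2000 × 5 library at ~100 reads/guide, the common design
target; a warning fires below 10×), `baseline_dispersion = 0.5` (guide
abundances spanning roughly an order of magnitude, as in real plasmid
pools), 2 replicates, 10% essential genes at effect −1, 2.5%
synthetic-viable at effect +2 (50 spiked among 2000, a strong but
plausible rescue), timepoints (1, 2) for the mid- and end-point
harvests, doses labeled after the motivating screen's two inhibitor
concentrations. The validation experiments (recovery, cross-screen) use
timepoints (0.5, 1.5) instead: the two-dose × two-timepoint layout is
retained, but mean exposure is one time unit so the measured logFC of a
spiked gene can be compared to its raw effect size 1:1 — that scaling
follows from the growth model, not from fitting.

What the simulator does **not** model: Cas9 cutting efficiency and
guide-to-guide efficacy variation, off-target effects, PCR jackpots,
cell-count bottlenecks between treatment rounds, dose-dependent effect
sizes (both doses get the same effect), or correlated replicate
batches. Passing recovery tests therefore show that the statistics
behave correctly on data matching the model's assumptions — clean
exponential selection with multinomial sequencing — not that the
pipeline is robust to every artifact of a wet screen; the
overdispersion knob covers only the simplest departure.

## Numerical choices and degenerate inputs

- KS p-values are clamped to `(tiny, 1]` so downstream BH never sees 0;
  a gene owning every guide in the table gives statistic 0, p = 1.
- BH is delegated to the standard step-up implementation and verified
  against a literal brute-force of the definition; inputs outside
  (0, 1] are rejected.
- `hypergeom_upper(k=0, ·) = 1` exactly; inconsistent arguments raise
  rather than return NaN.
- Result tables are serialized with 6 significant digits, ordered by
  (descending logFC, gene name), making reruns byte-identical.
- Readers reject malformed input (non-integer counts, duplicate guide
  ids or set names, ragged spacers, samples without metadata) with the
  offending record named; nothing is silently coerced.
- FASTQ guide counting is exact-match only (fixed offset or first-match
  scan); libraries with duplicate spacers are ambiguous and rejected.
  It is a convenience for simulated reads and simple amplicon designs,
  not a replacement for an aligner-based quantifier.

## Validation summary

The test suite checks, under fixed seeds: oracle equivalence of the
three core statistics against brute-force implementations; null
calibration and ≤1% hit rate after BH in a fully neutral screen;
recall ≥ 0.9 and false-discovery proportion ≤ 0.1 for 50 spiked genes
at effect 2.0 among 2000, with mean spiked logFC within ±0.2 of truth
and Pearson r ≥ 0.9 between truth and measurement across an effect
grid; ≥ 90% of spiked genes above relative score 1 against a no-rescue
control screen with a set-level hypergeometric p < 0.05 and exact score
reciprocality under screen exchange; and byte-level determinism plus
the worked filtering example (12 guides in 3 genes reducing to 8 guides
in 2 genes). `scripts/acceptance.py` recomputes all of these from
scratch at the problem sizes above, which keep the full run under a
minute of CPU.

## Known limitations

- The KS background includes the tested gene's own guides; for
  genome-scale libraries the contamination is negligible, for very
  small simulated libraries it biases the test slightly toward the
  null.
- Depletion-side (essentiality) calling is out of scope: essential
  genes appear with negative logFC but the hit definition is
  enrichment-only.
- The hypergeometric universes (analyzed genes; shared genes; DE-table
  genes) are taken from the inputs; with biased input universes the
  p-values inherit that bias.
- No guide-efficiency weighting, mean–variance modeling, or
  rank-aggregation alternatives (e.g. RRA-style statistics) are
  provided.
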