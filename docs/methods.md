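# Methods

## 1. Synthetic data model

The generator produces PSM-level tables for two experiment types sharing one
ground truth, so redox and abundance analyses can be cross-referenced per
protein.

### Ground truth (`simulate_ground_truth`)

For each of `n_proteins` (default 2000, a typical deep-coverage microalgal
proteome after filtering):

* **Base abundance** — log-normal with median `base_abundance_median`
  (default 1e5) and log-sd `base_abundance_sigma` (1.2), matching the
  several-orders-of-magnitude dynamic range of reporter intensities.
* **Differential abundance** — exactly `round(dap_fraction * n)` proteins
  (default 20%) get a true log2 fold change drawn uniformly from
  `log2fc_range` (1–4), with `dap_up_fraction` (0.45) of them up in HT.
  All other proteins have log2 FC = 0.
* **Redox stoichiometry** — each strain's per-protein reduced fraction is
  Beta-distributed, parameterized directly by mean and sd
  (HT 0.28 ± 0.15, LT 0.37 ± 0.19): with `ν = m(1−m)/v − 1`, the shapes are
  `a = mν`, `b = (1−m)ν`; the generator rejects infeasible moment pairs
  (`sd² ≥ m(1−m)`). In the default mode the two strains are sampled
  independently. In **paired mode** (`paired_redox=True`) the HT fraction is
  `min(r · LT, 1)` with `log r ~ N(log fc_pairing_median, fc_pairing_sigma)`
  (defaults 0.78 and 0.1), modeling a coherent per-protein oxidative shift.
* **Annotations** — disjoint top-level functional categories with one child
  term (a subset of its parent), each with a configurable bias toward the
  HT-up DAP pool, plus a `loc:<compartment>` term per protein. This gives
  enrichment analyses something real to find.
* **Merge groups** — `merge_group_size` proteins (default 18, labeled
  "LHCII") share near-identical peptides in practice and are analyzed as one
  summed group, as is standard for light-harvesting antenna families.

### PSM tables

Per protein, `1 + NB(mean, dispersion)` cysteine peptides (redox) or
peptides (abundance); each peptide has a log-normal response factor
(`peptide_factor_sigma = 0.8`), reflecting wide flyability differences.
Every intensity gets multiplicative log-normal noise with unit mean and
CV = `noise_cv` (0.1, a typical reporter-ion CV) and is missing completely
at random with `missing_rate` (0.05).

* **iodoTMT (redox)**: one 4-channel plex per replicate (default 4). Light
  channels 126/127 carry `A·f·g` for HT/LT (A = abundance, f = reduced
  fraction, g = peptide factor); heavy channels 130/131 carry `A·(1−f)·g`.
* **TMT-11plex (abundance)**: five replicates per strain; HT channels expect
  `A·g·2^(fc/2)`, LT channels `A·g·2^(−fc/2)`, and the 131C reference is the
  mean of the ten sample expectations. Channel 129N is **degenerate**
  (signal attenuated 100×, 50% extra missingness), emulating a failed label —
  the analysis must detect and drop it, leaving a 4-vs-5 comparison.

What the generator deliberately does **not** model: peptide-level
interference/co-isolation ratios compression, batch effects across plexes,
intensity-dependent missingness, and shared peptides between non-merged
proteins. These would change calibration constants but not the logic under
test.

### Determinism

All randomness flows from `numpy.random.default_rng([seed, stream_id])` with
separate streams for truth (0), iodoTMT PSMs (1), and TMT PSMs (2), so the
ground truth is identical across experiment types and runs are exactly
reproducible. Output TSVs are byte-stable (`%.9g` floats, empty string for
missing).

## 2. Redox analysis

1. **Roll-up**: PSM intensities are summed per protein × channel (a missing
   cell only when every contributing PSM is missing).
2. **Stoichiometry**: per (strain, replicate) pair,
   `s = light / (light + heavy)`; a missing side counts as zero signal, and
   `s` is missing only when both sides are missing or the total is zero.
3. **Replicate filter**: proteins quantified in ≥ `min_reps` (default 3)
   replicates per strain; the pipeline reports both the unfiltered and the
   filtered summaries.
4. **Comparison**: per protein, `fold_change` is the mean over replicates of
   the paired HT/LT stoichiometry ratio (replicates share a labeling run);
   `fc_ratio_of_means` (ratio of strain means) is also reported because the
   two definitions differ for skewed ratios. Per-protein two-sided
   homoscedastic t-tests get BH q-values; the strain-level shift is a paired
   t-test across proteins on the strain means. P-values below 2.2e-16
   (double-precision epsilon) are floored and displayed as "< 2.2e-16".
5. **Reproducibility**: pairwise Pearson correlations between replicate
   stoichiometry columns.

## 3. Abundance analysis

1. **Group merge** (optional): designated protein groups are summed into one
   row with provenance retained.
2. **Channel QC**: a channel is dropped when the median of the other
   channels' totals is ≥ `ratio_threshold` (100) times its own, or when its
   missing fraction exceeds `missing_frac` (0.5).
3. **Normalization**: one global factor per channel equalizing channel totals
   to their grand mean; then log2 and per-channel mean-centering (median
   optional).
4. **Moderated test**: `d = (mean_HT − mean_LT) / (se + s0)` with pooled
   homoscedastic `se` and `s0 = 1`, which damps the d of low-variance,
   low-effect proteins. Plain t-test p and BH q are reported alongside as a
   cross-check.
5. **Permutation FDR**: the null distribution of |d| comes from **balanced**
   label permutations — each permuted "group 1" contains half of its members
   (rounded both ways for odd sizes) from each true group. For 4 vs 5
   channels this is 60 exhaustible masks. With 20% strongly differential
   proteins, unbalanced permutations leak true signal into the null and
   destroy sensitivity; balancing cancels the group-mean difference in every
   permuted split. The threshold is the smallest |d| cutoff whose
   monotone-smoothed estimated FDR (median-free ratio of mean permuted
   exceedances to observed exceedances) is ≤ `target_fdr` (0.02).
6. **Clustering**: average-linkage hierarchical clustering (Euclidean) on
   rows and columns; rows are z-scored by default (`z_score=False` preserves
   raw log2 distances, under which identical columns merge at height 0).
   The two-way column partition is reported as a strain-recovery check.

## 4. Enrichment

* **Fisher exact** on the DAP / non-DAP × term-member / non-member 2×2
  table per term (scipy's exact implementation; verified in the tests
  against a direct hypergeometric summation). The universe is either all
  scored proteins or annotated proteins only. Terms with < 3 members are
  skipped.
* **1D annotation enrichment**: for each term, the rank-sum statistic of its
  members within the ranked score distribution, rescaled to
  `s = 2U/(n1·n2) − 1 ∈ [−1, 1]` (positive = members ranked high), with a
  tie-corrected normal approximation for p. Works on a single score vector
  or per-sample on a matrix.
* **Benjamini–Hochberg** is implemented in-package (reversed cumulative
  minimum over sorted p) and property-tested against the literal step-up
  definition.

## 5. Numerical choices

* P-value floor 2.2e-16 with "< 2.2e-16" display — below double epsilon the
  exact value is meaningless.
* `%.9g` TSV floats: round-trips float32-accurate data exactly and keeps
  files diff-able.
* NaN-aware vectorized t statistics (no per-row Python loops); zero pooled
  variance yields a missing p rather than ±inf.
* Balanced permutation masks are enumerated exhaustively when the count is
  small, otherwise sampled without replacement from a seeded generator.

## 6. Limitations

* FDR calibration is validated on the generator's noise model; heavy-tailed
  real data may need a larger `s0` or more permutations.
* The stoichiometry convention (missing side = zero signal) biases s toward
  0/1 for proteins detected on only one side; the replicate filter removes
  most such cases.
* The global scaling assumes equal total protein load per channel; it cannot
  correct composition effects.
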