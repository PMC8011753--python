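# Methods

This note records the models, defaults, numerical choices and known
limitations behind `pacseq`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Guide quantification

Guide-enriched read pairs carry the cell barcode and UMI on read 1
(lengths are configuration, defaults 16 + 10) and the guide cDNA on
read 2. Read 2 is aligned locally (Smith–Waterman, affine gaps) against
each guide's full sequence — spacer plus the invariant scaffold with its
poly-A tract. Defaults: match +1, mismatch −1, gap open −2, gap extend −1,
minimum accepted score 15. Because every guide shares the scaffold, a hit
additionally requires at least 15 aligned reference bases inside the
spacer (capped at the spacer length); reads scoring equally on two or more
guides are discarded as ambiguous. All scoring parameters are exposed —
the original pipeline's aligner settings are not published, so none of
these defaults is claimed as *the* setting, only as a reasonable one.
The alignment engine is Biopython's `PairwiseAligner`; the acceptance
rules (threshold, spacer coverage, ambiguity) are applied on top, and the
test suite checks scores against an independent Gotoh dynamic program.

Accepted hits are collapsed to one molecule per distinct (barcode, UMI,
guide) triple. No UMI error correction (e.g. Hamming-1 merging) is
performed — the simplest auditable rule — and when one (barcode, UMI)
pairs with two guides in different reads both triples are kept rather than
arbitrated; the downstream mixture model absorbs such noise.

## Guide-to-cell assignment

Per guide *g*, with *n_i* the cell's total gRNA UMI count and *k_i* its
count for *g* (cells with *n_i* = 0 are globally unassignable):

* model: `z_i ~ Bernoulli(π)`, `k_i | z_i ~ Binomial(n_i, p_{z_i})` with
  noise rate `p₀ < p₁` signal rate;
* initialisation: 2-component Gaussian mixture on the raw fractions
  `k_i/n_i` (raw rather than logit — the choice is inconsequential for the
  well-separated regimes the model targets and keeps zeros trivial);
  initial rates are the cluster means clipped into (1e−6, 1−1e−6), the
  initial weight is the cluster weight; coincident clusters are perturbed
  ±10% so EM can separate them; the GMM seed is an explicit parameter;
* EM: closed-form weighted updates `p_c = Σ r_ic k_i / Σ r_ic n_i`,
  `π = mean(r_signal)`; stop at log-likelihood gain < 1e−6 or 500
  iterations; rates clipped to [1e−6, 1−1e−6] against degenerate
  likelihoods. The log-likelihood trace is recorded and asserted
  non-decreasing (float round-off tolerance 1e−8 relative) on every fit;
* labels are ordered `p_noise < p_signal` after convergence, so the fit is
  invariant to initial labelling;
* degenerate data (all `k_i` = 0) short-circuits to an all-absent fit;
  fewer than `min_cells` (default 3) nonzero cells flags `low_support`.

Presence is called when the posterior noise probability is **strictly**
below the threshold (default 0.05); cells with exactly one present guide
are assigned. Cells present for zero or ≥2 guides are reported separately
(`none_present`, `multiple_present`) rather than folded into one
"unassigned" number, since published pool summaries are ambiguous on this
point. The detection rate divides assigned cells by the supplied
high-quality cell set; high-quality cells without any gRNA data count as
unassigned.

## Transcriptome QC and normalisation

* **Knee rule**: with `n = ceil(0.01 × expected_cells)` (so at least 100
  expected cells are required) and `T` the total of the n-th-ranked
  barcode, barcodes with totals strictly above `0.1 × T` are kept.
* **Outliers**: a retained cell is removed when its mitochondrial count
  fraction exceeds `median + 3·MAD`, or its `log1p` total counts or
  `log1p` genes detected fall below `median − 3·MAD`; MADs carry the
  normal-consistency factor 1.4826. Directions (high-only for
  mitochondrial load, low-only for depth metrics) and the log scale follow
  standard droplet-QC practice; both are configurable. `log1p` rather than
  a bare log keeps zero-count metrics finite. A zero MAD disables that
  metric with a warning, so homogeneous populations are never filtered.
  Mitochondrial genes are recognised by a configurable feature-name prefix
  (default the mouse convention `mt-`).
* **Normalisation**: `ln(1 + count × 1e4 / cell_total)` (scale factor
  configurable). Zero-total cells are an error — QC comes first.

## Differential expression

Two-sided Wilcoxon rank-sum per gene on log-normalised values, via
`scipy.stats.mannwhitneyu`. The exact permutation distribution is used
when both groups have ≤ 8 observations and the pooled values are tie-free;
otherwise the tie-corrected normal approximation with continuity
correction. The cross-over sits at 8 because a worst-case scan against
exact enumeration shows the asymptotic path can deviate by just over 0.01
at sizes (7,8)–(8,8) and shrinks beyond; with the exact path covering the
full ≤ 8 range the implementation is identical to enumeration there and
within ~0.01 above it. Fully tied pooled data yields p = 1. Genes with no
expression in either group are reported untested; by default they still
count toward the Bonferroni family size *m* (all genes in the matrix),
which is the conservative reading — *m* is configurable. Significance is
`adjusted p ≤ 0.05` (Bonferroni controls the family-wise error rate; the
correction is the simple `min(1, p·m)`). A gene is *consistently*
differentially expressed when it is significant with the same shift
direction in every population of guides targeting the same gene's
regulatory regions; the direction requirement can be disabled.

## Power simulation

Inputs: a control population's log-normalised profile and the expected
monoallelic/biallelic loss fractions `(f_mono, f_full)`,
`f_mono + f_full ≤ 1`. Procedure per repetition × bucket × treatment
size: draw one gene uniformly from the bucket; resample `n_treat` cells
with replacement from the control; independently label each cell
biallelic with probability `f_full` (value → 0) or monoallelic with
`f_mono` (value × 0.5); rank-sum test treatment against the full control
for that gene. Defaults: 10 equal-count (quantile) buckets — equal-width
is selectable, merging empty buckets — 100 repetitions, summarised by the
median p across reps (mean and rejection-fraction summaries are
selectable; the summary behind published contour surfaces is not stated
anywhere, and the median is robust for the heavy-tailed p distributions
involved). Adjusted surfaces multiply the per-rep p by the all-genes
family size `m_all` or by the independent-filtering size `m_b` (genes
whose mean baseline expression reaches the bucket's minimum), capped
at 1; `m_b ≤ m_all` makes filtered-adjusted ≤ all-adjusted pointwise,
and the per-bucket minimum cells required can only shrink. Loss is
applied to log-normalised values (halving the normalised value); for
count-space perturbation of raw matrices the synthetic-data module's
binomial 0.5-thinning is the analogue.

Randomness: one master seed; the substream for (rep, bucket) is
`default_rng([seed, rep, bucket])`, and within a rep the cell draws for
larger treatment sizes extend the smaller ones (common random numbers).
Grids are therefore bit-reproducible and p is monotone in `n_treat` and in
`f_full` up to a Monte-Carlo noise band estimated from the paired per-rep
differences.

**Known limitation — calibration at large n/N.** Because the treatment is
resampled *from* the control and tested *against the full* control,
conditional on the control the rank-sum z-statistic has variance
`N/(N+n)` of the independent-two-sample null (N control cells, n
treatment cells): the test is conservative by `sqrt((N+n)/N)` in the
z-score, e.g. nominal-0.05 rejection ≈ 0.029 at n = 500, N = 2000. This
is a property of the resampling design itself, pushes power estimates in
the safe (pessimistic) direction, and vanishes as n/N → 0; the type-I
calibration checks in the acceptance suite therefore run at n = 100
against a 2000-cell control (theoretical rejection 0.045). Uniformity of
null p-values is checked on the top expression bucket, where the rank-sum
null distribution is approximately continuous; in near-zero-expression
buckets the test is discrete and conservative, which is also why the
lowest buckets' rejection rates sit below nominal.

## Synthetic data

The generators emulate the statistical structure of droplet scRNA-seq,
not any specific dataset:

* transcriptomes: gamma-Poisson (negative binomial,
  `var = m(1 + φm)`, default φ = 0.1; φ = 0 is the Poisson limit) with
  log-normal per-cell depth factors (σ = 0.3), 1000 genes with means
  log-spaced over 0.02–30 UMIs/cell so all ten expression buckets
  populate and the median cell carries ~4k UMIs; ten mitochondrial genes
  scaled to a 5% count share;
* guide libraries: 10 guides (one per pooled population), per-cell totals
  negative-binomial around 150 UMIs — matching the order of magnitude of
  published per-cell guide readouts — with the true guide receiving
  `Binomial(n_i, 0.95)` and the remainder spread over the other guides at
  noise rate 0.005, so marginal per-guide counts are the bimodal
  signal+noise mixture the assignment model assumes;
* perturbations: default loss (0.25, 0.05), the observed regime for
  maximally disruptive cis-regulatory guides (~20–30% some loss, <5%
  biallelic);
* barcode-rank distributions: real cells at the transcriptome depth,
  ambient barcodes log-normal around 30 UMIs (<1% of a real cell),
  producing a sharp knee;
* reads: one pair per molecule (configurable), per-base substitution
  errors, UMIs distinct within a cell so error-free quantification
  round-trips exactly.

Every generator is a pure function of (configuration, seed), with
separate derived streams per generator. What passing tests on these
fixtures do **not** show: robustness to ambient guide contamination,
barcode swapping, doublets, batch effects, or non-NB expression — none of
which are modelled.

## Problem sizes in the standard runs

The shipped suite and acceptance script use 2000-cell × 1000-gene control
populations, 800–5000-cell screens, 100-rep power grids (1000 reps for
the uniformity check), and 10⁴-draw loss-expectation checks — sizes at
which every documented tolerance is comfortably resolvable while a full
run stays in the tens of seconds.
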