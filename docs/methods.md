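# Methods

## Data model

Input is a per-cytosine methylation call table per sample (tab-delimited:
chrom, 1-based position, strand, methylated count, unmethylated count,
context), a targeted-panel BED, and a sample manifest describing patient
trios (TUM / ADJ / DIS) with QC covariates. Only CpG and CHH contexts are
used: CpG carries the methylation signal, CHH carries the
conversion-failure signal; CHG lines are dropped on read. Complementary CpG
strand calls are collapsed into one unit anchored at the plus-strand
position with summed counts. Coordinates are 1-based in cytosine reports
(upstream caller convention) and 0-based half-open in every emitted BED.

Sample inclusion follows the trio design: tumor samples below a 10% tumor
cell fraction and normal samples with any visible tumor cell (a boolean
manifest flag, since histology review is not computable) are excluded, and
any patient left without a complete TUM+ADJ+DIS trio is dropped entirely.

Missing is distinct from zero throughout: a block-sample entry with no CpG
coverage is NaN, and paired tests drop patients pairwise per comparison
(no imputation).

## Block segmentation

Neighbouring CpGs on a panel tend to be co-methylated. Segmentation is a
greedy left-to-right scan within each panel region; a consecutive pair is
merged iff

* Pearson r of their methylation fractions across samples ≥ `r_min`
  (default 0.5), computed over pairwise-complete samples (≥ 3 required);
* genomic distance ≤ `d_max_bp` (default 500);
* absolute difference of across-sample mean levels ≤ `level_diff_max`
  (default 0.3).

A missing correlation (too few samples, or a zero-variance site) never
merges — conservative against false co-methylation. The three gates are
deliberately separate rather than one trained composite score: each is
testable in isolation, and published composite coefficients for this kind
of segmentation are generally trained on proprietary multi-tissue panels.
The scan is deterministic and order-independent given sorted input; the
result always partitions the panel's CpGs, and raising `r_min` can only
split, never merge (block count is monotone in `r_min`). Blocks never span
two panel regions, since targeted gaps make cross-region correlation
meaningless. CHH sites attach to the covering block, else the nearest block
in the same region.

Annotation assigns each block a category with priority
promoter > exon > intron > intergenic on any overlap, with promoter =
[TSS − 2000, TSS + 500) strand-aware (a conventional choice; "promoter" has
no universal definition), recording all overlapping gene names. Gene models
are read from BED12.

## Corrected block methylation

Per (block, sample), CpG counts are pooled into methylMean = ΣM/Σ(M+U) and
CHH counts into error = ΣMe/Σ(Me+Ue); the corrected value is
(methylMean − error)/(1 − error), clamped into [0, 1] (fractions are
bounded; the correction can undershoot zero by sampling noise). Under the
error model observed = e + (1 − e)·π this is an exact inverse in
expectation, and correction is order-preserving at fixed error.

The scope of the CHH pool is configurable because block-level CHH coverage
is often thin: the default uses the block's own CHH reads when at least
`min_chh_reads = 20` are available and falls back to the sample-wide CHH
pool otherwise (`error_source` records which); an alternative mode always
uses the sample pool. Per-site depth below `min_depth = 5` is treated as
uncovered (reads that thin carry more noise than signal; the threshold is
exposed).

## Differential testing

Values are tested on the log2(x + 0.01) scale by default (`value_transform`;
identity available). Per-block paired differences (TUM − DIS for
tumor-specific calls; ADJ − DIS, TUM − ADJ, TUM − DIS for the trio analysis)
are tested with a variance-moderated paired t: the per-block sample variance
s² on d = n − 1 degrees of freedom is shrunk toward a scaled
inverse-chi-square prior (d0, s0²) fitted across blocks by matching the
first two moments of log s² (digamma/trigamma moments of the log-F
distribution; the trigamma inverse is solved by Newton iteration), giving
s̃² = (d0·s0² + d·s²)/(d0 + d) and t = mean/(s̃/√n) on d + d0 df. d0 = 0
reduces bitwise to the ordinary paired t; d0 = ∞ pools completely. Fewer
than 3 complete pairs yields a missing result; a zero-variance block gives
t = 0, p = 1 when the mean difference is zero and a flagged degenerate
p = 0 otherwise.

Tumor-specific DMRs pass both gates |log2FC| > 0.1 and BH-adjusted
p < 0.05, with log2FC = log2((mean_TUM + ε)/(mean_DIS + ε)), ε = 0.01, on
group means over pairwise-complete patients. The ratio scale (rather than
a linear-model coefficient on fractions) is used because reported fold
changes in this literature reach values impossible as fraction differences;
the offset keeps near-zero means finite. Direction is hyper/hypo by the
sign of the paired mean difference.

FC (stepwise) calls require, per block: within-block Bonferroni over the
three trio contrasts (×3, capped at 1), across-block adjustment per
contrast (BH default; Bonferroni available), both *adjacent* contrasts
(ADJ−DIS and TUM−ADJ) significant with same-sign differences, and strictly
monotone group means. The TUM−DIS contrast is reported but not gated —
adjacent steps are the minimal faithful reading of "stepwise". Emitted
blocks always satisfy their category's strict ordering (asserted in tests).

Multiple-testing adjustment is implemented directly (BH step-up
p·m/rank with enforced monotonicity; Bonferroni min(1, m·p)) and
cross-checked against statsmodels in the test suite; NaN entries are
ignored for the correction and returned NaN in place.

## Enrichment

The enrichment unit is the gene (a gene hit by several blocks counts once).
With N universe genes, K set genes, n query genes and k overlap, the
over-representation p is the inclusive upper tail P(X ≥ k) of the
hypergeometric distribution — the standard convention for
over-representation tests — evaluated through scipy's log-gamma-based
survival function and verified against exhaustive enumeration. The gene
set (e.g. transcription factors) is an input file, one symbol per line;
the universe defaults to all genes spanned by the panel's blocks.

## Synthetic trio generator

The generator emulates the statistical structure of a targeted trio study;
its defaults are the study conditions used by the validation suite:

| parameter | default | meaning |
|---|---|---|
| n_patients | 36 | complete TUM/ADJ/DIS trios |
| n_blocks | 1000 | desk-scale panel (scalable) |
| sites_per_block / chh_per_block | 3–12 / 1–4 | member CpG / CHH sites |
| depth_mean, depth_dispersion | 60, 5 | negative-binomial read depth |
| baseline mixture | 0.7·Beta(1,10) + 0.3·Beta(10,1) | mostly-unmethylated vs mostly-methylated blocks |
| n_tumor_hyper / hypo / fc_up / fc_down | 200 / 10 / 40 / 5 | planted classes, roughly proportional to reported DMR yields |
| delta_tumor / delta_fc | 0.25 / 0.15 | effect sizes on the fraction scale |
| patient_sd | 0.3 | logit-scale patient random effect |
| rho | 0.05 | beta-binomial intra-class correlation |
| conversion_failure_range | U[0.002, 0.02] | per-sample e_s |

Effects are additive on the fraction scale and ADJ sits exactly midway for
stepwise classes (DIS = μ, ADJ = μ ± δ/2, TUM = μ ± δ) — the simplest
embodiment of a stepwise field — while patient heterogeneity alone is
logit-scale and shared across a patient's three tissues, so it cancels in
paired contrasts. Planted-effect blocks redraw their baseline from the same
mixture until baseline plus shift fits within [0.02, 0.98]; otherwise
boundary clamping would destroy the strict ordering the truth table
guarantees. Conversion failure is the only asymmetric error channel (no
inappropriate conversion of methylated cytosines): this is exactly the
channel the correction formula inverts, which is what makes the
correction-recovery check sharp. CHH sites have true π = 0 and read out
e_s. All draws come from one numpy Generator in a fixed order (block-level
draws → site layout → sample-level draws → read counts), so config + seed
reproduce the dataset byte for byte; the beta step of the beta-binomial is
drawn as a ratio of two float32 standard-gamma variates (≈4× faster than
the generic beta sampler, accurate far below read-count resolution).

What the generator does **not** emulate: genomic sequence context, panel
bait dropout, inappropriate conversion of methylated cytosines,
copy-number or purity variation in tumors, batch effects, and spatially
varying conversion efficiency. Passing tests therefore demonstrate
correctness of the machinery under the stated error model, not robustness
to every artifact of real libraries.

A consequence of the stated conditions worth knowing: at depth 60 with
rho = 0.05 the beta-binomial noise floor per site exceeds the
between-sample variance of *null* blocks (patient_sd 0.3), so adjacent-pair
correlations mostly fall below r_min = 0.5 and default-scale synthetic
panels over-segment. The calibration and recovery checks therefore
quantify the callers on the generating blocks, while the end-to-end
segmentation-recovery test uses a strong-signal configuration (depth 150,
patient_sd 0.8) in which co-methylation is identifiable. On real panels the
co-methylation gates should be tuned on reference tissue series — the
published segmentations of this kind do exactly that, and the trained
coefficients are exposed here as `BlockParams`.

## Pipeline and numerics

The pipeline runs simulate/load → segment → quantify → test → enrich →
PCA in fixed order, single-threaded and deterministic; every output
carries a config-hash comment line, identical config + seed gives
byte-identical bundles, each stage can be rerun from the previous stage's
files, and a failed stage removes its partial outputs and names itself in
the raised error. PCA is a report convenience only: per-block mean
imputation of missing entries, centered SVD (scikit-learn), sample
coordinates written as TSV — no clustering claims beyond the observable
tumor/normal separation on strong effects.

Numerical conventions: corrected values clamp to [0, 1]; error estimates
clip just below 1 to keep the correction defined; correlations with
near-zero variance are treated as missing rather than ±1; p-value
adjustment preserves input order and NaN positions; the trigamma inverse
uses Newton iteration with the asymptotic branches for extreme arguments;
all-equal sample variances short-circuit to d0 = ∞ with the common
variance as prior.

## Validation problem sizes

The suite validates at sizes chosen to make the statistical assertions
sharp while keeping a desk-scale footprint: correction bias on 800 null
blocks at depth 100 (bias bound ±0.01); type-I error of the ordinary
paired t on 10,000 null blocks and the BH false-discovery proportion over
20 seeds of the same; stepwise recovery on 20 seeds of 1000 blocks with
200 planted fc_up each (sensitivity ≥ 0.8, FDR ≤ 0.1) and tumor recovery
with 100 planted tumor_hyper (sensitivity ≥ 0.8, all hyper); variance-prior
recovery from 5000 simulated variances; and oracle equivalence of BH,
the hypergeometric tail (all N ≤ 25), moderation at d0 = 0, and
segmentation against brute-force rule application.

## Known limitations

* The segmentation gates are placeholders to be tuned per panel; the
  package cannot reproduce any particular published block set without the
  panel and training tissues.
* The moderated test assumes approximately normal paired differences of
  block values; heavily bimodal blocks (tumor subclones) violate this.
* The error correction assumes conversion failure is the only asymmetric
  error; FFPE deamination artifacts and mapping bias are out of scope.
* The enrichment test conditions on the panel's gene universe; it cannot
  speak to genome-wide enrichment.
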