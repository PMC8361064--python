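# Methods

## Scope and data model

`methylcna` operates on count tables, not reads: per-sample per-bin
methylated/total CpG counts and aligned read counts over a fixed 1 Mb
autosomal bin registry, per-region methylated/unmethylated CpG counts
for a targeted panel, UMI-tagged aligned read strings per locus, and a
cohort sample sheet. Alignment, bisulfite methylation extraction,
somatic variant calling and segmentation are upstream tools' jobs and
out of scope. Coordinates are 0-based half-open (BED convention). Only
chr1–chr22 are accepted; sex-chromosome labels are rejected with an
error rather than silently dropped, so a mis-configured registry cannot
skew genome-wide fractions.

## Genome-wide calling rules

**Hypomethylation.** Bin methylation density MD = meth_C / total_C is
reported only when total_C ≥ `min_cpg_obs` (default 10 CpG
observations; at ~0.6× depth a 1 Mb bin typically has thousands, so the
threshold only guards near-empty bins). A bin is hypomethylated when
MD < mean − 3·SD of the healthy reference for that bin, with strict
inequality and the SD multiplier configurable. Only the hypo direction
is called genome-wide. The per-sample hypomethylated-bin fraction uses
evaluable bins as its denominator so missingness does not deflate the
statistic; evaluable-bin counts are reported alongside.

**Copy number.** Raw counts are corrected by a LOESS fit of count on GC
fraction (span 0.3 by default, the QDNAseq-style choice; correction
factors are rescaled to mean 1 so the genome-wide count level is
preserved), median-normalized across bins, and z-scored against the
healthy baseline. A bin is a CNA when |z| > 3, strict and two-sided.
Below 30 bins or 3 distinct GC values a LOESS is not meaningful, so a
median-per-GC-stratum correction is used; with a single GC stratum the
correction is the identity and a warning is raised. Fitted LOESS values
are floored at 1% of their median to avoid sign flips in sparse GC
tails.

**Pipeline symmetry.** Healthy reference samples are pushed through the
identical GC-correct → median-normalize path before the baseline
mean/SD are computed. Any asymmetry here destroys the z-score's null
calibration, which the test suite checks explicitly.

**Degenerate bins.** Bins where any reference subject lacks MD, or
where either reference SD is zero, are marked non-evaluable and excluded
from both calling rules (they would otherwise demand division by zero);
they are flagged in the persisted baseline. Sample SD uses the n−1
denominator throughout.

## Panel differential methylation

Per region, %methylation = 100·meth_C/(meth_C+unmeth_C), missing when
the region has no coverage. Groups are compared with the Wilcoxon
rank-sum test: exact enumeration null when the combined n is ≤ 20 with
no ties (the intended 11-vs-8 group sizes make exactness cheap),
otherwise the normal approximation with tie and continuity corrections.
P-values are Benjamini–Hochberg adjusted in a single family across all
tested regions (not per direction). A region is called hyper/hypo when
q < 0.05 and log2((mean_A + ε)/(mean_B + ε)) exceeds ±1, both strict;
the pseudocount ε = 1 percentage point makes the fold change finite for
fully unmethylated regions. Group means (not medians or paired ratios)
define the fold change; this is a config option. Regions missing in
more than half of either group's samples are excluded from testing and
reported with a reason, and q-values are computed over tested regions
only.

## UMI consensus and VAF

Reads sharing a UMI form a family; per position the consensus keeps a
base only when strictly more than 50% of the family's reads carry it,
writing N otherwise — an exact 50/50 tie is deliberately a no-call,
since the underlying rule ("errors carried by a minority are
eliminated") does not adjudicate ties. N reads count against the
majority denominator. `min_family_size` defaults to 1 (every fragment
is used) with a strict mode available. VAF is the percentage of
consensus fragments carrying the alternate base at the locus; fragments
with N there are excluded from numerator and denominator both.

## Cohort statistics

Pearson correlations are reported with Fisher-z 95% confidence
intervals and two-sided t-test p-values plus a least-squares line; the
CI is returned as the vacuous (−1, 1) at n = 3 and degenerates to a
point at |r| = 1, where the transform is undefined. Two-group contrasts
use the same rank-sum core as the panel; three or more groups use
Kruskal–Wallis (ranks are the defensible choice for VAF-like data).
Summary-table percentages are rounded half-up to one decimal. Group
assignment: a patient is *on-target* when the detected resistance set
intersects {T790M, EGFR amplification}, *off-target* when it is
non-empty and contained in {MET, HER2 amplification}, and *unknown*
otherwise (unknowns are excluded from group contrasts).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at the study's scale: a 20-subject healthy reference; ~7,000 reads and
~12,000 CpG observations per 1 Mb bin (the 20 M-read, ~0.6× setting;
the mapping from depth to per-bin CpG observations is not physically
derived, so `cpg_obs_mean` is a free parameter); per-subject per-bin
methylation probability Normal(0.70, 0.03) truncated to [0, 1] with
binomial CpG sampling on top; negative-binomial read counts with
dispersion 0.002 (extra CV ≈ 4.5%, mild sWGS-like over-dispersion that
keeps the count null near-normal — a dial for robustness testing, not a
fitted value); and a smooth quadratic GC bias, the simplest shape the
LOESS corrector must remove.

On-target patients carry an exact number of hypomethylated bins
(fraction × bins, shifted down by `hypo_effect_sds`·SD, default 8) and
contiguous CNA segments (geometric lengths, mean 20 bins, one random
sign per segment, shifted by `cna_effect_sds` count-SDs, default 6).
CNA segments are drawn first and the hypo set is then built to contain
a configurable fraction (default 0.8) of the CNA bins, which induces
the strong cross-sample hypomethylation–CNA correlation the cohort
contrast tests for. Off-target patients are drawn from the healthy
model. EGFR-amplified patients additionally get a focal multiplication
of the EGFR-locus bins and a time-to-treatment-resistance coupled to
their CNA burden with loading ρ (default 0.9). Panel simulation uses
202 hyper-target regions (baseline methylation 0.2, +0.6 in on-target),
58 hypo-targets (0.8, −0.6) and 190 nulls on a fixed grid, ~200 CpG
observations per region. Every sample records its generating truth.

What the generator does **not** emulate: fragment-level biology
(fragment size, nucleosome positioning), mappability and blacklist
structure, bin-to-bin correlated baseline methylation profiles,
tumor-fraction-driven joint scaling of all signals, or subclonal
mixtures. Passing tests therefore demonstrate that the calling rules
and statistics behave correctly under their stated model — calibrated
nulls, unbiased recovery of planted effects, correct inference — not
that the pipeline is robust to every artifact of real plasma data.

## Calibration experiments and problem sizes

The validation experiments (also driven by `scripts/acceptance.py`) use
a reduced 22 × 46 Mb genome (1,012 bins) where only the per-bin law
matters, and the full hg38 registry (2,887 bins) elsewhere; sizes were
chosen so the whole suite runs in well under a minute per experiment on
one core.

The null-calibration experiment fits its baseline on a 400-subject
reference rather than 20. This is deliberate: the event
MD < m̂ − 3ŝ with estimated mean and SD is a Student-t tail, not
Φ(−3) — at n = 20 its probability is P(t₁₉ < −3/√(1+1/20)) ≈ 0.0043,
three times the large-sample limit. With 400 reference subjects the
expected rate is ≈ 0.00145 (hypo) and ≈ 0.0029–0.0032 (two-sided CNA,
slightly above 2Φ(−3) from residual count skewness), isolating the
calibration of the calling rule itself from reference-estimation noise.
Consequence for practice: against a 20-subject baseline the *expected*
null hypomethylated-bin fraction is ~0.4%, and off-target/healthy
samples should be read against that floor, not against Φ(−3).

Parameter-recovery runs use the study-scale 20-subject reference (the
~0.4%/0.9% null floors are well inside the ±0.02 recovery tolerance at
effect sizes 8 and 6 SD). DMR recovery uses 20 replicate 11-vs-8
cohorts; UMI suppression uses 10,000 families of size 3 at 5% per-base
error.

## Known limitations

- The amplification score (mean normalized-count ratio over a gene's
  bins) is a proxy read-out on a ratio scale; it is not comparable in
  absolute value to allele-specific copy-number callers and carries no
  purity/ploidy correction.
- Whether to z-score normalized counts or log-ratios is a genuine
  fork; the implementation z-scores normalized counts, matching the
  plain reading of the median-normalization recipe. Log-ratio z-scores
  would compress amplifications and stretch deletions.
- No segmentation: CNA calls are per-bin, so a fragmented segment
  contributes each bin independently to the CNA fraction.
- The exact rank-sum null assumes no ties; percentage data from small
  CpG counts can tie, in which case the tie-corrected normal
  approximation is used even at small n.
- TTTR correlations at n = 6 are distribution-level statements;
  individual seeds legitimately vary (the test suite asserts sign and
  significance over a majority of seeds, not per-seed values).
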