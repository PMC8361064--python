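# methylcna

Liquid-biopsy analysis of EGFR-TKI resistance in non-small-cell lung
cancer from plasma cell-free DNA (cfDNA): genome-wide methylation
density and copy-number aberration calling from low-pass bisulfite
sequencing counts, targeted-panel differential methylation, UMI
consensus deduplication with fragment-level variant allele frequencies,
and the cohort statistics that link these molecular read-outs to
resistance-mutation groups. A synthetic cfDNA cohort generator with
recorded ground truth makes every stage testable without sequencing
data.

## Who this is for

Bioinformaticians working with shallow (~0.6×) whole-genome bisulfite
cfDNA data who want reproducible, healthy-baseline-referenced calls of
genome-wide hypomethylation and copy-number instability, and
statisticians validating such pipelines against simulated cohorts with
known truth.

## The model

The 22 autosomes are tiled into 1 Mb bins. For sample *s* and bin *b*,
the **methylation density** is

    MD(s, b) = methylated CpG cytosines / total CpG cytosines

and bin *b* is **hypomethylated** when

    MD(s, b) < mean_H(b) − 3 · SD_H(b)

with mean/SD taken over a healthy reference cohort (sample SD, n−1
denominator; strict inequality). The per-sample statistic is the
fraction of evaluable bins called hypomethylated.

For copy number, raw per-bin read counts are GC-corrected with a LOESS
fit of count on GC fraction (QDNAseq-style), median-normalized across
bins, and converted to per-bin z-scores against the healthy baseline
processed through the identical path:

    z(s, b) = (x(s, b) − mean_H(b)) / SD_H(b)

A bin is a **copy-number aberration (CNA)** when z > 3 or z < −3
(strict), and the per-sample statistic is the CNA-bin fraction. Focal
gene amplification is summarized as the mean normalized-count ratio
over the gene's bins versus the healthy mean.

Panel regions are compared between patient groups on
%methylation = 100·meth_C/(meth_C + unmeth_C) with the Wilcoxon
rank-sum test (exact when the combined sample is ≤ 20 and tie-free),
Benjamini–Hochberg correction across tested regions, and a
|log2 fold change| > 1, FDR < 0.05 call. UMI families are collapsed to
consensus fragments keeping only bases supported by strictly more than
50% of reads (ties → N); VAF is the percentage of informative consensus
fragments carrying the alternate allele. Group contrasts use
Mann–Whitney / Kruskal–Wallis tests and Pearson correlations with
Fisher-z 95% confidence intervals.

## Worked example

```sh
methylcna run --seed 7 --out-dir demo_out
```

simulates a 20-subject healthy reference plus a 19-patient cohort
(11 patients with EGFR-dependent "on-target" resistance carrying
coupled genome-wide hypomethylation and segmental CNA, 8 "off-target"
MET/HER2-amplified patients drawn from the healthy model), then runs
baseline fitting, hypomethylation and CNA calling, panel DMR testing
and the cohort statistics. It prints:

```
on-target mean hypo fraction  0.358
off-target mean hypo fraction 0.0042
Mann-Whitney p (hypo)         3.24e-04
hypo~CNA Pearson r            0.998 (95% CI 0.99-1.00)
DMR calls                     202 hyper, 58 hypo of 450 regions
outputs written to demo_out
```

Reading: on-target patients average 35.8% hypomethylated bins versus
0.42% for off-target patients (the off-target value sits at the null
calling rate of the 3-SD rule against a 20-subject baseline); the group
difference is significant by Mann–Whitney; hypomethylation and CNA
burden correlate almost perfectly across the 19 patients because the
generator couples the two perturbations (overlap 0.8); and all 202
hyper- plus 58 hypo-methylated panel regions built into the simulation
are recovered, with no false calls among the 190 null regions.
`demo_out/` holds the baseline, per-sample summaries, the DMR table,
the sample × region %methylation matrix, ground truth and a run
manifest, all as TSV/JSON. The same analysis runs on user-supplied
count tables via the `baseline`, `methylome`, `cna`, `dmr`, `consensus`
and `stats` subcommands, or `stats.run_pipeline` with
`PipelineConfig(input_dir=...)`.

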