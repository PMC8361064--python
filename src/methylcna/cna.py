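"""Shallow-WGS copy-number aberration calls from per-bin read counts.

The pipeline follows the QDNAseq-style recipe: raw per-bin read counts
are corrected for GC bias with a LOESS fit of count on GC fraction,
median-normalized across bins, and converted to per-bin z-scores against
the healthy baseline.  A bin is a copy-number aberration (CNA) when
|z| > 3 (strict), and the per-sample statistic is the fraction of
evaluable bins flagged.  Healthy reference samples must be pushed
through the identical correct -> normalize path before fitting the
baseline, otherwise the z-score loses its null calibration.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomicBin, ReferenceBaseline, check_same_registry

__all__ = [
    "DEFAULT_LOESS_SPAN",
    "CnaProfile",
    "CnaSummary",
    "AmplificationScore",
    "gc_correct",
    "median_normalize",
    "cna_zscores",
    "call_cna",
    "summarize_cna",
    "amplification_score",
    "process_counts",
    "write_cna_profile_tsv",
]

DEFAULT_LOESS_SPAN = 0.3
#: Below this many bins (or <3 distinct GC values) LOESS is unreliable;
#: a median-per-GC-stratum correction is used instead.
MIN_BINS_FOR_LOESS = 30


@dataclass
class CnaProfile:
    sample_id: str
    bins: list[GenomicBin]
    raw_count: np.ndarray
    corrected_count: np.ndarray | None = None
    normalized_count: np.ndarray | None = None
    z: np.ndarray | None = None
    cna_flag: np.ndarray | None = None


@dataclass(frozen=True)
class CnaSummary:
    sample_id: str
    n_evaluable_bins: int
    n_cna_bins: int
    cna_fraction: float


@dataclass(frozen=True)
class AmplificationScore:
    """Mean normalized-count ratio over a gene's bins vs the healthy mean.

    A proxy read-out on a ratio scale (1 = no amplification in
    expectation); not comparable in absolute value to allele-specific
    copy-number callers.
    """

    gene: str
    score: float
    mean_z: float
    n_bins: int


def gc_correct(
    raw_counts,
    gc_fraction,
    span: float = DEFAULT_LOESS_SPAN,
) -> np.ndarray:
    """Divide counts by a LOESS fit of count on GC, mean correction 1.

    With fewer than ``MIN_BINS_FOR_LOESS`` bins or fewer than 3 distinct
    GC values the LOESS is replaced by a median-per-GC-stratum factor;
    with a single GC stratum the correction is the identity (warned).
    """
    raw = np.asarray(raw_counts, dtype=float)
    gc = np.asarray(gc_fraction, dtype=float)
    if raw.shape != gc.shape or raw.ndim != 1:
        raise ValueError("raw_counts and gc_fraction must be aligned 1-D arrays")
    if np.any(raw < 0):
        raise ValueError("negative read counts")
    distinct = np.unique(gc[~np.isnan(gc)])
    if distinct.size <= 1:
        warnings.warn(
            "all GC fractions identical; GC correction is the identity",
            stacklevel=2,
        )
        return raw.copy()
    if raw.size < MIN_BINS_FOR_LOESS or distinct.size < 3:
        # stratum-median fallback for tiny bin sets
        fhat = np.empty_like(raw)
        for g in distinct:
            sel = gc == g
            fhat[sel] = np.median(raw[sel])
    else:
        fhat = lowess(
            raw, gc, frac=span, return_sorted=False,
            delta=0.01 * (distinct.max() - distinct.min()),
        )
    # guard against non-positive fitted values in sparse GC tails
    floor = 0.01 * np.median(fhat[fhat > 0]) if np.any(fhat > 0) else 1.0
    fhat = np.maximum(fhat, floor)
    factor = 1.0 / fhat
    factor /= factor.mean()
    return raw * factor


def median_normalize(corrected_counts) -> np.ndarray:
    """Divide every bin by the median count over all (finite) bins."""
    counts = np.asarray(corrected_counts, dtype=float)
    finite = counts[np.isfinite(counts)]
    if finite.size == 0 or not np.any(finite > 0):
        raise ValueError("median normalization requires at least one positive count")
    med = np.median(finite)
    if med == 0:
        raise ValueError("median read count is zero; cannot normalize")
    return counts / med


def cna_zscores(normalized_counts, baseline: ReferenceBaseline) -> np.ndarray:
    """(x - count_mean) / count_sd per bin; NaN where non-evaluable."""
    x = np.asarray(normalized_counts, dtype=float)
    if x.shape != (len(baseline.bins),):
        raise ValueError(
            f"{x.size} counts for {len(baseline.bins)} baseline bins"
        )
    z = np.full(x.shape, np.nan)
    ok = baseline.evaluable & np.isfinite(x)
    z[ok] = (x[ok] - baseline.count_mean[ok]) / baseline.count_sd[ok]
    return z


def call_cna(
    profile: CnaProfile, baseline: ReferenceBaseline, z_cut: float = 3.0
) -> CnaProfile:
    """Populate z and cna_flag (|z| strictly above ``z_cut``)."""
    check_same_registry(profile.bins, baseline.bins)
    if profile.normalized_count is None:
        raise ValueError("normalized_count not populated; run process_counts first")
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    z = cna_zscores(profile.normalized_count, baseline)
    flag = np.full(z.shape, np.nan)
    ok = ~np.isnan(z)
    flag[ok] = ((z[ok] > z_cut) | (z[ok] < -z_cut)).astype(float)
    return dataclasses.replace(profile, z=z, cna_flag=flag)


def summarize_cna(profile: CnaProfile) -> CnaSummary:
    if profile.cna_flag is None:
        raise ValueError("cna_flag not populated; run call_cna first")
    flag = np.asarray(profile.cna_flag, dtype=float)
    evaluable = ~np.isnan(flag)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError(f"sample {profile.sample_id}: zero evaluable bins")
    n_cna = int(np.nansum(flag))
    return CnaSummary(
        sample_id=profile.sample_id,
        n_evaluable_bins=n_eval,
        n_cna_bins=n_cna,
        cna_fraction=n_cna / n_eval,
    )


def amplification_score(
    profile: CnaProfile,
    gene_bins: Sequence[int],
    baseline: ReferenceBaseline,
    gene: str = "gene",
) -> AmplificationScore:
    """Mean normalized_count / baseline count_mean over the gene's bins."""
    idx = np.asarray(gene_bins, dtype=int)
    if idx.size == 0:
        raise ValueError("gene_bins is empty")
    if profile.normalized_count is None:
        raise ValueError("normalized_count not populated")
    ok = baseline.evaluable[idx]
    if not np.any(ok):
        raise ValueError(f"gene {gene}: no evaluable bins")
    idx = idx[ok]
    ratio = profile.normalized_count[idx] / baseline.count_mean[idx]
    z = (profile.normalized_count[idx] - baseline.count_mean[idx]) / baseline.count_sd[idx]
    return AmplificationScore(
        gene=gene,
        score=float(ratio.mean()),
        mean_z=float(z.mean()),
        n_bins=int(idx.size),
    )


def process_counts(
    sample_id: str,
    raw_counts,
    bins: Sequence[GenomicBin],
    baseline: ReferenceBaseline | None = None,
    span: float = DEFAULT_LOESS_SPAN,
    z_cut: float = 3.0,
) -> CnaProfile:
    """Full per-sample path: GC-correct -> median-normalize [-> z, flags]."""
    raw = np.asarray(raw_counts, dtype=float)
    gc = np.array([b.gc_fraction for b in bins])
    corrected = gc_correct(raw, gc, span=span)
    normalized = median_normalize(corrected)
    profile = CnaProfile(
        sample_id=sample_id,
        bins=list(bins),
        raw_count=raw,
        corrected_count=corrected,
        normalized_count=normalized,
    )
    if baseline is not None:
        profile = call_cna(profile, baseline, z_cut=z_cut)
    return profile


def write_cna_profile_tsv(profile: CnaProfile, path) -> None:
    frame = pd.DataFrame(
        {
            "chrom": [b.chrom for b in profile.bins],
            "start": [b.start for b in profile.bins],
            "end": [b.end for b in profile.bins],
            "raw_count": profile.raw_count,
        }
    )
    for col in ("corrected_count", "normalized_count", "z", "cna_flag"):
        val = getattr(profile, col)
        if val is not None:
            frame[col] = val
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
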