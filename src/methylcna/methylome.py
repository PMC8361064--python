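"""Per-bin methylation density and genome-wide hypomethylation calls.

Methylation density (MD) of a bin is the fraction of methylated
cytosines among all cytosines observed at CpG positions in that bin.  A
bin is called hypomethylated when its MD falls strictly more than three
healthy-cohort SDs below the healthy mean for the same bin; the
per-sample summary statistic is the fraction of evaluable bins so
called.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomicBin, ReferenceBaseline, check_same_registry

__all__ = [
    "DEFAULT_MIN_CPG_OBS",
    "BinProfile",
    "MethylomeSummary",
    "methylation_density",
    "call_hypomethylated",
    "summarize_methylome",
    "write_bin_profile_tsv",
    "read_bin_counts_tsv",
]

#: Minimum CpG observations per bin for the density to be reported.
DEFAULT_MIN_CPG_OBS = 10


def methylation_density(
    meth_c, total_c, min_cpg_obs: int = DEFAULT_MIN_CPG_OBS
):
    """meth_c / total_c per bin; NaN where total_c < min_cpg_obs.

    Accepts scalars or aligned arrays of non-negative counts with
    meth_c <= total_c elementwise.
    """
    meth = np.asarray(meth_c, dtype=float)
    total = np.asarray(total_c, dtype=float)
    if np.any(meth < 0) or np.any(total < 0):
        raise ValueError("counts must be non-negative")
    if np.any(meth > total):
        raise ValueError("methylated count exceeds total CpG count")
    with np.errstate(invalid="ignore", divide="ignore"):
        md = np.where(total >= min_cpg_obs, meth / total, np.nan)
    if np.isscalar(meth_c) and np.isscalar(total_c):
        return float(md)
    return md


@dataclass
class BinProfile:
    """One sample's per-bin CpG counts, densities and hypomethylation flags.

    ``md`` is NaN where the bin had fewer than ``min_cpg_obs`` CpG
    observations; ``hypo_flag`` (0/1 floats) is NaN wherever ``md`` is
    missing or the baseline bin is non-evaluable, and None before
    :func:`call_hypomethylated` has run.
    """

    sample_id: str
    bins: list[GenomicBin]
    meth_c: np.ndarray
    total_c: np.ndarray
    md: np.ndarray | None = None
    hypo_flag: np.ndarray | None = None
    min_cpg_obs: int = DEFAULT_MIN_CPG_OBS

    def __post_init__(self) -> None:
        n = len(self.bins)
        if np.shape(self.meth_c) != (n,) or np.shape(self.total_c) != (n,):
            raise ValueError("count arrays must have one entry per registry bin")
        if self.md is None:
            self.md = methylation_density(self.meth_c, self.total_c, self.min_cpg_obs)


@dataclass(frozen=True)
class MethylomeSummary:
    sample_id: str
    n_evaluable_bins: int
    n_hypo_bins: int
    hypo_fraction: float


def call_hypomethylated(
    profile: BinProfile,
    baseline: ReferenceBaseline,
    sd_multiplier: float = 3.0,
) -> BinProfile:
    """Flag bins with MD strictly below baseline mean - multiplier * SD.

    Bins missing MD in the sample or non-evaluable in the baseline get a
    NaN flag and never enter downstream fractions.
    """
    check_same_registry(profile.bins, baseline.bins)
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    md = np.asarray(profile.md, dtype=float)
    usable = ~np.isnan(md) & baseline.evaluable
    threshold = baseline.md_mean - sd_multiplier * baseline.md_sd
    flag = np.full(md.shape, np.nan)
    flag[usable] = (md[usable] < threshold[usable]).astype(float)
    return dataclasses.replace(profile, hypo_flag=flag)


def summarize_methylome(profile: BinProfile) -> MethylomeSummary:
    """Hypomethylated-bin fraction over evaluable bins only."""
    if profile.hypo_flag is None:
        raise ValueError("hypo_flag not populated; run call_hypomethylated first")
    flag = np.asarray(profile.hypo_flag, dtype=float)
    evaluable = ~np.isnan(flag)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError(f"sample {profile.sample_id}: zero evaluable bins")
    n_hypo = int(np.nansum(flag))
    return MethylomeSummary(
        sample_id=profile.sample_id,
        n_evaluable_bins=n_eval,
        n_hypo_bins=n_hypo,
        hypo_fraction=n_hypo / n_eval,
    )


def write_bin_profile_tsv(profile: BinProfile, path) -> None:
    frame = pd.DataFrame(
        {
            "chrom": [b.chrom for b in profile.bins],
            "start": [b.start for b in profile.bins],
            "end": [b.end for b in profile.bins],
            "meth_c": np.asarray(profile.meth_c, dtype=int),
            "total_c": np.asarray(profile.total_c, dtype=int),
            "md": profile.md,
        }
    )
    if profile.hypo_flag is not None:
        frame["hypo_flag"] = profile.hypo_flag
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bin_counts_tsv(path, sample_id: str | None = None, **kwargs) -> BinProfile:
    """Load a per-sample TSV of chrom, start, end, meth_c, total_c."""
    frame = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "meth_c", "total_c"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bins = [
        GenomicBin(str(r.chrom), int(r.start), int(r.end))
        for r in frame.itertuples(index=False)
    ]
    return BinProfile(
        sample_id=sample_id or str(path),
        bins=bins,
        meth_c=frame["meth_c"].to_numpy(),
        total_c=frame["total_c"].to_numpy(),
        **kwargs,
    )
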