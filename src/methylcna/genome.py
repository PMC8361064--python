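"""Autosomal 1 Mb bin registry and healthy-reference baselines.

Every genome-wide signal in this package (methylation density,
copy-number z-scores) is expressed per fixed-width bin over the 22
autosomes and judged against a baseline estimated from a cohort of
healthy plasma samples.  This module owns the bin registry, its BED-like
persistence, and the per-bin mean/SD baseline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUTOSOMES",
    "HG38_AUTOSOME_LENGTHS",
    "GenomicBin",
    "ReferenceBaseline",
    "build_bin_registry",
    "fit_baseline",
    "registry_to_frame",
    "frame_to_registry",
    "write_registry_bed",
    "read_registry_bed",
    "write_baseline_tsv",
    "read_baseline_tsv",
    "check_same_registry",
    "bins_overlapping",
]

#: Autosome labels accepted everywhere; sex chromosomes are rejected, not dropped.
AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

#: hg38 autosome lengths (bp); the default genome for full-scale runs.
HG38_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True)
class GenomicBin:
    """One fixed-width genomic bin, 0-based half-open (BED convention)."""

    chrom: str
    start: int
    end: int
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(
                f"non-autosomal chromosome label {self.chrom!r}; "
                f"only chr1-chr22 are supported"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid bin interval [{self.start}, {self.end})")
        gc = self.gc_fraction
        if not np.isnan(gc) and not (0.0 <= gc <= 1.0):
            raise ValueError(f"gc_fraction {gc} outside [0, 1]")


def build_bin_registry(
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    gc_fractions: Sequence[float] | None = None,
) -> list[GenomicBin]:
    """Tile each autosome from 0 to its length with ``bin_size`` bins.

    The last bin of a chromosome may be shorter than ``bin_size``.  Bins
    are ordered chr1..chr22, then by start.  ``gc_fractions``, if given,
    must have one value per resulting bin (in registry order).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    for label in chrom_lengths:
        if label not in AUTOSOMES:
            raise ValueError(
                f"non-autosomal chromosome label {label!r}; only chr1-chr22 are supported"
            )
    bins: list[GenomicBin] = []
    for chrom in AUTOSOMES:
        if chrom not in chrom_lengths:
            continue
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, bin_size):
            bins.append(GenomicBin(chrom, start, min(start + bin_size, length)))
    if gc_fractions is not None:
        gc = np.asarray(gc_fractions, dtype=float)
        if gc.shape != (len(bins),):
            raise ValueError(
                f"gc_fractions has {gc.size} values for {len(bins)} bins"
            )
        bins = [
            GenomicBin(b.chrom, b.start, b.end, float(g)) for b, g in zip(bins, gc)
        ]
    return bins


def registry_to_frame(bins: Sequence[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "gc_fraction": [b.gc_fraction for b in bins],
        }
    )


def frame_to_registry(frame: pd.DataFrame) -> list[GenomicBin]:
    return [
        GenomicBin(str(r.chrom), int(r.start), int(r.end), float(r.gc_fraction))
        for r in frame.itertuples(index=False)
    ]


def write_registry_bed(bins: Sequence[GenomicBin], path) -> None:
    """4-column BED-like TSV: chrom, start, end, gc_fraction (no header)."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.gc_fraction!r}\n")


def read_registry_bed(path) -> list[GenomicBin]:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gc_fraction"],
        float_precision="round_trip",
    )
    return frame_to_registry(frame)


def check_same_registry(
    bins_a: Sequence[GenomicBin], bins_b: Sequence[GenomicBin]
) -> None:
    """Raise if the two registries differ, naming the first discordant bin."""
    if len(bins_a) != len(bins_b):
        raise ValueError(
            f"bin registries differ in length: {len(bins_a)} vs {len(bins_b)}"
        )
    for i, (a, b) in enumerate(zip(bins_a, bins_b)):
        if (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end):
            raise ValueError(
                f"bin registries diverge at index {i}: "
                f"{a.chrom}:{a.start}-{a.end} vs {b.chrom}:{b.start}-{b.end}"
            )


def bins_overlapping(
    bins: Sequence[GenomicBin], chrom: str, start: int, end: int
) -> np.ndarray:
    """Indices of registry bins overlapping [start, end) on ``chrom``."""
    return np.array(
        [
            i
            for i, b in enumerate(bins)
            if b.chrom == chrom and b.start < end and b.end > start
        ],
        dtype=int,
    )


@dataclass
class ReferenceBaseline:
    """Per-bin healthy-cohort mean/SD for methylation density and counts.

    A bin is evaluable only when every healthy subject contributed a
    methylation density there and both SDs are strictly positive (a zero
    SD would make the 3-SD / z-score rules degenerate).
    """

    n_subjects: int
    bins: list[GenomicBin]
    md_mean: np.ndarray
    md_sd: np.ndarray
    count_mean: np.ndarray
    count_sd: np.ndarray
    evaluable: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.bins)
        for name in ("md_mean", "md_sd", "count_mean", "count_sd", "evaluable"):
            arr = getattr(self, name)
            if np.shape(arr) != (n,):
                raise ValueError(
                    f"baseline field {name} has shape {np.shape(arr)}, expected ({n},)"
                )
        ok = self.evaluable
        if np.any(self.md_sd[ok] < 0) or np.any(self.count_sd[ok] < 0):
            raise ValueError("negative SD in baseline")
        md_ok = self.md_mean[ok]
        if md_ok.size and (np.nanmin(md_ok) < 0 or np.nanmax(md_ok) > 1):
            raise ValueError("md_mean outside [0, 1] on evaluable bins")

    @property
    def n_evaluable(self) -> int:
        return int(self.evaluable.sum())


def fit_baseline(
    md: np.ndarray,
    counts: np.ndarray,
    bins: Sequence[GenomicBin],
) -> ReferenceBaseline:
    """Fit the healthy reference from aligned subject x bin matrices.

    ``md`` holds per-subject per-bin methylation densities (NaN where a
    subject has no density for a bin); ``counts`` holds the matching
    normalized read counts.  Sample SD uses the n-1 denominator.  Bins
    where any subject is missing MD, or where either SD is zero, are
    marked non-evaluable.
    """
    md = np.asarray(md, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if md.ndim != 2 or counts.shape != md.shape:
        raise ValueError("md and counts must be 2-D arrays of identical shape")
    n_subjects, n_bins = md.shape
    if n_subjects < 2:
        raise ValueError(
            f"baseline requires at least 2 healthy subjects (got {n_subjects}); "
            "the sample SD is undefined otherwise"
        )
    if n_bins != len(bins):
        raise ValueError(f"{n_bins} columns for {len(bins)} registry bins")

    md_mean = md.mean(axis=0)
    md_sd = md.std(axis=0, ddof=1)
    count_mean = counts.mean(axis=0)
    count_sd = counts.std(axis=0, ddof=1)

    complete = ~np.isnan(md).any(axis=0) & ~np.isnan(counts).any(axis=0)
    evaluable = complete & (md_sd > 0) & (count_sd > 0)
    return ReferenceBaseline(
        n_subjects=n_subjects,
        bins=list(bins),
        md_mean=md_mean,
        md_sd=md_sd,
        count_mean=count_mean,
        count_sd=count_sd,
        evaluable=evaluable,
    )


_BASELINE_COLUMNS = [
    "chrom", "start", "end",
    "md_mean", "md_sd", "count_mean", "count_sd", "evaluable",
]


def write_baseline_tsv(baseline: ReferenceBaseline, path) -> None:
    frame = pd.DataFrame(
        {
            "chrom": [b.chrom for b in baseline.bins],
            "start": [b.start for b in baseline.bins],
            "end": [b.end for b in baseline.bins],
            "md_mean": baseline.md_mean,
            "md_sd": baseline.md_sd,
            "count_mean": baseline.count_mean,
            "count_sd": baseline.count_sd,
            "evaluable": baseline.evaluable.astype(int),
        }
    )
    buf = io.StringIO()
    buf.write(f"# n_subjects={baseline.n_subjects}\n")
    frame.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_baseline_tsv(path) -> ReferenceBaseline:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# n_subjects="):
            raise ValueError(f"{path}: missing n_subjects header line")
        n_subjects = int(header.strip().split("=", 1)[1])
        frame = pd.read_csv(fh, sep="\t")
    missing = set(_BASELINE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing baseline columns {sorted(missing)}")
    bins = [
        GenomicBin(str(r.chrom), int(r.start), int(r.end))
        for r in frame.itertuples(index=False)
    ]
    return ReferenceBaseline(
        n_subjects=n_subjects,
        bins=bins,
        md_mean=frame["md_mean"].to_numpy(float),
        md_sd=frame["md_sd"].to_numpy(float),
        count_mean=frame["count_mean"].to_numpy(float),
        count_sd=frame["count_sd"].to_numpy(float),
        evaluable=frame["evaluable"].to_numpy(bool),
    )
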