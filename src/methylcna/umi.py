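"""UMI read-family consensus and fragment-level variant allele frequency.

Reads sharing a unique molecular identifier (UMI) derive from one
original cfDNA fragment, so sequencing and PCR errors appear in only
some reads of a family.  The consensus keeps, per position, the base
supported by strictly more than 50% of the family's reads and writes N
otherwise (including exact 50/50 ties), eliminating errors carried by a
minority of reads.  Variant allele frequency (VAF) is then the
percentage of consensus fragments carrying the alternate base at a
locus, with N fragments excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UmiFamily",
    "ConsensusFragment",
    "VafEstimate",
    "group_by_umi",
    "consensus",
    "vaf",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class UmiFamily:
    umi: str
    reads: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError(f"UMI family {self.umi!r} has no reads")
        length = len(self.reads[0])
        for read in self.reads:
            if len(read) != length:
                raise ValueError(
                    f"UMI family {self.umi!r}: reads have unequal lengths "
                    f"({length} vs {len(read)})"
                )
            bad = set(read) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"UMI family {self.umi!r}: invalid bases {sorted(bad)}"
                )


@dataclass(frozen=True)
class ConsensusFragment:
    umi: str
    consensus: str
    family_size: int


@dataclass(frozen=True)
class VafEstimate:
    locus: str
    alt_fragments: int
    total_fragments: int
    vaf: float  # percent


def group_by_umi(
    tagged_reads: Iterable[tuple[str | None, str]]
) -> tuple[list[UmiFamily], int]:
    """Group (umi, read) pairs into families, lexicographic UMI order.

    Reads with a missing/empty UMI are dropped; the second return value
    counts them.
    """
    buckets: dict[str, list[str]] = {}
    dropped = 0
    for umi, read in tagged_reads:
        if not umi:
            dropped += 1
            continue
        buckets.setdefault(umi, []).append(read)
    families = [
        UmiFamily(umi=umi, reads=tuple(reads))
        for umi, reads in sorted(buckets.items())
    ]
    return families, dropped


def consensus(
    family: UmiFamily, min_family_size: int = 1
) -> ConsensusFragment | None:
    """Majority-vote consensus; positions without a >50% base become N.

    Families smaller than ``min_family_size`` are discarded (None).
    The majority denominator is the full family size, so N reads at a
    position count against every candidate base.
    """
    k = len(family.reads)
    if k < min_family_size:
        return None
    length = len(family.reads[0])
    out = []
    half = k / 2.0
    for pos in range(length):
        counts: dict[str, int] = {}
        for read in family.reads:
            base = read[pos]
            if base != "N":
                counts[base] = counts.get(base, 0) + 1
        best = max(counts.items(), key=lambda kv: kv[1], default=("N", 0))
        out.append(best[0] if best[1] > half else "N")
    return ConsensusFragment(
        umi=family.umi, consensus="".join(out), family_size=k
    )


def vaf(
    fragments: Sequence[ConsensusFragment],
    locus: int,
    ref: str,
    alt: str,
    locus_label: str = "",
) -> VafEstimate:
    """Percent of informative consensus fragments carrying ``alt``.

    Fragments with N at the locus are uninformative and excluded from
    both counts.
    """
    if ref == alt:
        raise ValueError("ref and alt bases must differ")
    bases = [f.consensus[locus] for f in fragments]
    informative = [b for b in bases if b != "N"]
    if not informative:
        raise ValueError(f"no informative consensus fragments at locus {locus}")
    alt_n = sum(b == alt for b in informative)
    total = len(informative)
    return VafEstimate(
        locus=locus_label or str(locus),
        alt_fragments=alt_n,
        total_fragments=total,
        vaf=100.0 * alt_n / total,
    )
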