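"""Targeted-panel differential methylation between patient groups.

Each panel region (typically a CpG island in a promoter or enhancer)
yields a per-sample methylation percentage
100 * meth_C / (meth_C + unmeth_C).  Regions are compared between two
groups with the Wilcoxon rank-sum test (exact when the combined sample
is small and tie-free, normal approximation with tie and continuity
corrections otherwise), p-values are Benjamini-Hochberg adjusted across
all tested regions, and a region is called differentially methylated
when q < 0.05 and |log2 fold change| of group mean percentages
(with a pseudocount) exceeds 1 — both strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PanelRegion",
    "region_methylation",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "call_dmrs",
    "write_panel_bed",
    "read_panel_bed",
    "pct_matrix_from_counts",
]

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_MAX_N = 20


@dataclass(frozen=True)
class PanelRegion:
    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    n_cpg: int = 0


def region_methylation(meth_c, unmeth_c):
    """100 * meth / (meth + unmeth); NaN when a region has no coverage."""
    meth = np.asarray(meth_c, dtype=float)
    unmeth = np.asarray(unmeth_c, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("CpG counts must be non-negative")
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * meth / total, np.nan)
    if np.isscalar(meth_c) and np.isscalar(unmeth_c):
        return float(pct)
    return pct


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration null when the combined n is at most
    ``EXACT_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    pct: pd.DataFrame,
    groups: pd.Series | dict,
    group_a: str,
    group_b: str,
    log2fc_cut: float = 1.0,
    fdr_cut: float = 0.05,
    pseudocount: float = 1.0,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Test every panel region for differential methylation A vs B.

    ``pct`` is a samples x regions matrix of methylation percentages
    (NaN = no coverage); ``groups`` maps sample id -> group label.
    Regions missing in more than ``max_missing_fraction`` of either
    group's samples are excluded from testing and reported with
    ``tested = False``.  log2fc is log2((mean_A + e) / (mean_B + e))
    with pseudocount ``e`` in percentage points; q-values are computed
    across tested regions only.  ``call`` is "hyper"/"hypo" (in A
    relative to B) under strict cuts, else "none".
    """
    groups = pd.Series(groups)
    a_samples = groups.index[groups == group_a]
    b_samples = groups.index[groups == group_b]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"need >=2 samples per group (got {len(a_samples)} {group_a!r}, "
            f"{len(b_samples)} {group_b!r})"
        )
    missing_a = set(a_samples) - set(pct.index)
    missing_b = set(b_samples) - set(pct.index)
    if missing_a or missing_b:
        raise ValueError(
            f"samples missing from the pct matrix: {sorted(missing_a | missing_b)}"
        )

    rows = []
    for region in pct.columns:
        va = pct.loc[a_samples, region].to_numpy(float)
        vb = pct.loc[b_samples, region].to_numpy(float)
        n_a = int(np.sum(~np.isnan(va)))
        n_b = int(np.sum(~np.isnan(vb)))
        frac_missing_a = 1 - n_a / len(a_samples)
        frac_missing_b = 1 - n_b / len(b_samples)
        tested = (
            frac_missing_a <= max_missing_fraction
            and frac_missing_b <= max_missing_fraction
            and n_a >= 2
            and n_b >= 2
        )
        mean_a = float(np.nanmean(va)) if n_a else np.nan
        mean_b = float(np.nanmean(vb)) if n_b else np.nan
        if tested:
            log2fc = float(
                np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
            )
            p = wilcoxon_rank_sum(va, vb)
            reason = ""
        else:
            log2fc, p = np.nan, np.nan
            reason = "insufficient coverage"
        rows.append(
            {
                "region_id": region,
                "n_a": n_a,
                "n_b": n_b,
                "mean_pct_a": mean_a,
                "mean_pct_b": mean_b,
                "log2fc": log2fc,
                "p": p,
                "tested": tested,
                "reason": reason,
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = np.nan
    tested_mask = result["tested"].to_numpy()
    if tested_mask.any():
        result.loc[tested_mask, "q"] = bh_adjust(result.loc[tested_mask, "p"])
    call = np.full(len(result), "none", dtype=object)
    sig = tested_mask & (result["q"].to_numpy() < fdr_cut)
    call[sig & (result["log2fc"].to_numpy() > log2fc_cut)] = "hyper"
    call[sig & (result["log2fc"].to_numpy() < -log2fc_cut)] = "hypo"
    result["call"] = call
    return result


def pct_matrix_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy (sample, region_id, meth_c, unmeth_c) table to pct.

    Returns a samples x regions matrix suitable for :func:`call_dmrs`
    and for export to external clustering / heatmap tools.
    """
    required = {"sample", "region_id", "meth_c", "unmeth_c"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    counts = counts.copy()
    counts["pct"] = region_methylation(
        counts["meth_c"].to_numpy(), counts["unmeth_c"].to_numpy()
    )
    return counts.pivot(index="sample", columns="region_id", values="pct")


def write_panel_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.gene}\n")


def read_panel_bed(path) -> list[PanelRegion]:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "region_id", "gene"],
    )
    return [
        PanelRegion(
            region_id=str(r.region_id), gene=str(r.gene),
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
        )
        for r in frame.itertuples(index=False)
    ]
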