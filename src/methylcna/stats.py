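"""Cohort-level statistics and pipeline orchestration.

Implements the statistical layer tying genome-wide methylation and
copy-number read-outs to resistance-mutation groups: Pearson
correlations with Fisher-z confidence intervals and least-squares fits
(hypomethylation vs CNA, instability vs time to treatment resistance),
exact/approximate rank tests for group contrasts, Kruskal-Wallis for
multi-group VAF comparisons, cohort summary tables, and ``run_pipeline``
which drives generate -> baseline -> methylome -> cna -> panel -> stats
end to end.  Also hosts the calibration experiments (null calibration,
parameter recovery, DMR recovery, UMI error suppression) used to
validate the whole stack.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cna as cna_mod
from . import genome, methylome, panel, simulate, umi

__all__ = [
    "PatientRecord",
    "CorrelationResult",
    "pearson_with_ci",
    "mann_whitney",
    "kruskal_wallis",
    "cohort_summary",
    "round_half_up",
    "demo_cohort_sheet",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "null_calibration",
    "recovery_experiment",
    "dmr_recovery_experiment",
    "umi_suppression_experiment",
]

ON_TARGET_MUTATIONS = frozenset({"T790M", "EGFR_amp"})
OFF_TARGET_MUTATIONS = frozenset({"MET_amp", "HER2_amp"})


@dataclass(frozen=True)
class PatientRecord:
    """One patient's mutation profile, clinical covariates and read-outs.

    ``resistance`` is the (possibly empty) set of detected resistance
    mutations; a patient is on-target when it contains T790M or EGFR
    amplification, off-target when it is non-empty and contains only
    MET/HER2 amplification, and unknown otherwise.
    """

    patient_id: str
    sensitizing: str = "none"  # del19 | L858R | rare | none
    resistance: frozenset = frozenset()
    sex: str = "Unknown"
    histology: str = "Unknown"
    stage: str = "Unknown"
    tki_regimen: str = "Unknown"
    sensitizing_vaf: float = float("nan")
    t790m_vaf: float = float("nan")
    amplification_score: float = float("nan")
    tttr_days: float = float("nan")
    hypo_fraction: float = float("nan")
    cna_fraction: float = float("nan")

    @property
    def group(self) -> str:
        res = frozenset(self.resistance)
        if res & ON_TARGET_MUTATIONS:
            return "on_target"
        if res and res <= OFF_TARGET_MUTATIONS:
            return "off_target"
        return "unknown"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    slope: float
    intercept: float


def pearson_with_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z CI, two-sided t-test p, least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3 pairs (got {n})")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    if n > 3 and abs(r) < 1.0:
        zr = np.arctanh(r)
        half = sps.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
        ci_low, ci_high = np.tanh(zr - half), np.tanh(zr + half)
    else:
        # Fisher z is undefined at n = 3 or |r| = 1; the CI is vacuous
        ci_low, ci_high = (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    return CorrelationResult(
        r=float(r), ci_low=float(ci_low), ci_high=float(ci_high),
        p=float(p), n=n, slope=float(fit.slope), intercept=float(fit.intercept),
    )


def mann_whitney(group_a, group_b) -> float:
    """Two-sided Mann-Whitney p; shares its core with the panel's test."""
    return panel.wilcoxon_rank_sum(group_a, group_b)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal-Wallis p (chi-square approximation, tie-corrected)."""
    if len(groups) < 3:
        raise ValueError(
            "Kruskal-Wallis needs >= 3 groups; use mann_whitney for two"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 1.0  # H = 0 when every observation is identical
    return float(sps.kruskal(*arrays).pvalue)


def round_half_up(value: float, digits: int = 1) -> float:
    """Decimal half-up rounding (table-style percentages)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _profile_label(resistance: frozenset) -> str:
    return "+".join(sorted(resistance)) if resistance else "none_detected"


def cohort_summary(records: Sequence[PatientRecord]) -> dict:
    """Counts and half-up percentages per clinical / mutation category.

    Returns a dict with per-category tables (level, count, pct) and the
    headline fractions: patients with any resistance mutation, retention
    of the del19/L858R sensitizing mutation among resistance-positive
    patients, and co-occurrence of additional resistance mutations among
    T790M-positive patients.
    """
    if not records:
        raise ValueError("cohort_summary needs at least one record")
    n = len(records)

    def table(values: Sequence[str]) -> pd.DataFrame:
        counts = pd.Series(values).value_counts()
        frame = pd.DataFrame(
            {
                "level": counts.index,
                "count": counts.to_numpy(),
                "pct": [round_half_up(100.0 * c / n) for c in counts],
            }
        )
        return frame.sort_values(
            ["count", "level"], ascending=[False, True]
        ).reset_index(drop=True)

    categories = {
        "sex": table([r.sex for r in records]),
        "histology": table([r.histology for r in records]),
        "stage": table([r.stage for r in records]),
        "tki_regimen": table([r.tki_regimen for r in records]),
        "resistance_profile": table(
            [_profile_label(frozenset(r.resistance)) for r in records]
        ),
        "group": table([r.group for r in records]),
    }

    resistant = [r for r in records if frozenset(r.resistance)]
    retained = [r for r in resistant if r.sensitizing in ("del19", "L858R")]
    t790m = [r for r in records if "T790M" in r.resistance]
    co_occurring = [r for r in t790m if len(frozenset(r.resistance)) > 1]

    def frac(k: int, d: int) -> dict:
        return {
            "count": k,
            "denominator": d,
            "pct": round_half_up(100.0 * k / d) if d else 0.0,
        }

    return {
        "n": n,
        "categories": categories,
        "resistance_detected": frac(len(resistant), n),
        "sensitizing_retained": frac(len(retained), len(resistant)),
        "t790m_cooccurrence": frac(len(co_occurring), len(t790m)),
    }


def demo_cohort_sheet() -> list[PatientRecord]:
    """A 122-patient demonstration sample sheet.

    Reproduces a realistic composition for an EGFR-TKI acquired
    resistance cohort: 51 patients with a detected resistance mutation
    (T790M alone or with PIK3CA / EGFR amplification, EGFR amplification
    alone, MET or HER2 amplification), 46 of whom retain their del19 or
    L858R sensitizing mutation, and 71 with no detected resistance
    mechanism.
    """
    composition: list[tuple[int, frozenset, bool]] = [
        # (count, resistance profile, sensitizing retained)
        (23, frozenset({"T790M"}), True),
        (7, frozenset({"T790M"}), True),   # with rare EGFR co-mutations
        (4, frozenset({"T790M", "PIK3CA"}), True),
        (5, frozenset({"T790M", "EGFR_amp"}), True),
        (3, frozenset({"EGFR_amp"}), True),
        (4, frozenset({"MET_amp"}), False),
        (4, frozenset({"HER2_amp"}), True),
        (1, frozenset({"HER2_amp"}), False),
        (71, frozenset(), True),
    ]
    sex = ["Female"] * 71 + ["Male"] * 48 + ["Unknown"] * 3
    histology = ["AC"] * 85 + ["SCC"] * 4 + ["Unknown"] * 33
    stage = ["III-IV"] * 100 + ["Unknown"] * 22
    tki = (
        ["erlotinib"] * 82 + ["gefitinib"] * 14
        + ["erlotinib+gefitinib"] * 2 + ["afatinib"] * 3
        + ["erlotinib+afatinib"] * 3 + ["Unknown"] * 18
    )
    records = []
    i = 0
    for count, profile, retained in composition:
        for _ in range(count):
            records.append(
                PatientRecord(
                    patient_id=f"P{i + 1:03d}",
                    sensitizing=("del19" if i % 2 == 0 else "L858R")
                    if retained else "none",
                    resistance=profile,
                    sex=sex[i],
                    histology=histology[i],
                    stage=stage[i],
                    tki_regimen=tki[i],
                )
            )
            i += 1
    assert len(records) == 122
    return records


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline settings.

    By default the pipeline simulates its cohort; pointing ``input_dir``
    at a directory holding bins.bed, sample_sheet.tsv (sample, group
    columns; groups healthy / on_target / off_target), per-sample
    ``<sample>.tsv`` bin tables (chrom, start, end, meth_c, total_c,
    raw_count) and panel_counts.tsv (sample, region_id, meth_c,
    unmeth_c) runs the identical analysis on those tables instead.
    """

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    panel: simulate.PanelSimConfig = field(
        default_factory=simulate.PanelSimConfig
    )
    cohort: tuple[simulate.PatientSimConfig, ...] | None = None
    input_dir: str | Path | None = None
    tttr_rho: float = 0.9
    sd_multiplier: float = 3.0
    z_cut: float = 3.0


@dataclass
class _CohortData:
    """Uniform in-memory cohort, whether simulated or loaded."""

    bins: list
    healthy: list  # SyntheticSample-like (sample_id, meth_c, total_c, read_count)
    patients: list
    designs: list  # (PatientSimConfig, resistance frozenset) per patient
    panel_tidy: pd.DataFrame
    truth: dict


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return path


def _load_cohort(input_dir: Path) -> _CohortData:
    bins = genome.read_registry_bed(_require(input_dir / "bins.bed"))
    sheet = pd.read_csv(_require(input_dir / "sample_sheet.tsv"), sep="\t")
    panel_tidy = pd.read_csv(_require(input_dir / "panel_counts.tsv"), sep="\t")

    def load_sample(sid: str, group: str) -> simulate.SyntheticSample:
        frame = pd.read_csv(_require(input_dir / f"{sid}.tsv"), sep="\t")
        return simulate.SyntheticSample(
            sample_id=sid, group=group,
            meth_c=frame["meth_c"].to_numpy(),
            total_c=frame["total_c"].to_numpy(),
            read_count=frame["raw_count"].to_numpy(),
        )

    healthy, patients, designs = [], [], []
    default_res = {
        "on_target": frozenset({"T790M"}),
        "off_target": frozenset({"MET_amp"}),
    }
    for row in sheet.itertuples(index=False):
        sid, group = str(row.sample), str(row.group)
        sample = load_sample(sid, group)
        if group == "healthy":
            healthy.append(sample)
        else:
            patients.append(sample)
            res = (
                frozenset(str(row.resistance).split(","))
                if "resistance" in sheet.columns and pd.notna(row.resistance)
                else default_res[group]
            )
            tttr = (
                float(row.tttr_days)
                if "tttr_days" in sheet.columns else float("nan")
            )
            designs.append(
                (
                    simulate.PatientSimConfig(
                        patient_id=sid, group=group, tttr_days=tttr
                    ),
                    res,
                )
            )
    return _CohortData(
        bins=bins, healthy=healthy, patients=patients,
        designs=designs, panel_tidy=panel_tidy,
        truth={s.sample_id: s.truth for s in patients},
    )


def _simulate_cohort(config: PipelineConfig) -> _CohortData:
    sim = simulate.CohortSimulator(config.simulation)
    healthy = sim.healthy()
    designs = (
        [
            (p, frozenset({"T790M"}) if p.group == "on_target"
             else frozenset({"MET_amp"}))
            for p in config.cohort
        ]
        if config.cohort is not None
        else _default_cohort_design(sim, config.tttr_rho)
    )
    patients = [sim.patient(pconf) for pconf, _ in designs]
    rows = []
    for s in patients:
        meth, unmeth, _t = sim.panel(s.group, config.panel)
        rows.extend(
            {
                "sample": s.sample_id,
                "region_id": f"region_{i + 1:04d}",
                "meth_c": int(m),
                "unmeth_c": int(u),
            }
            for i, (m, u) in enumerate(zip(meth, unmeth))
        )
    return _CohortData(
        bins=sim.bins, healthy=healthy, patients=patients,
        designs=designs, panel_tidy=pd.DataFrame(rows),
        truth={s.sample_id: s.truth for s in patients},
    )


def _default_cohort_design(
    sim: simulate.CohortSimulator, rho: float
) -> list[tuple[simulate.PatientSimConfig, frozenset]]:
    """The 19-patient contrast the demo pipeline runs.

    11 on-target patients (5 T790M, 3 EGFR-amplified, 3 with both)
    carrying genome-wide hypomethylation coupled to segmental CNA, and
    8 off-target patients (4 MET-, 4 HER2-amplified) drawn from the
    healthy model.  EGFR-amplified patients get a focal amplification at
    the EGFR locus and a TTTR coupled to their CNA burden with
    correlation ``rho``.
    """
    rng = sim.rng
    cfg = sim.config
    chr7_len = cfg.chrom_lengths.get("chr7", 0)
    if chr7_len >= 56_000_000:
        amp_bins = genome.bins_overlapping(
            sim.bins, "chr7", 55_000_000, 55_200_000
        )
    else:  # small genomes: middle bin of chr7
        chr7 = [i for i, b in enumerate(sim.bins) if b.chrom == "chr7"]
        amp_bins = np.array(chr7[len(chr7) // 2 : len(chr7) // 2 + 1])

    profiles = (
        [("T790M", frozenset({"T790M"}))] * 5
        + [("EGFRamp", frozenset({"EGFR_amp"}))] * 3
        + [("T790M-EGFRamp", frozenset({"T790M", "EGFR_amp"}))] * 3
        + [("METamp", frozenset({"MET_amp"}))] * 4
        + [("HER2amp", frozenset({"HER2_amp"}))] * 4
    )
    designs = []
    resid = np.sqrt(1 - rho**2)
    for i, (tag, res) in enumerate(profiles):
        pid = f"{tag}-{i + 1:02d}"
        on = bool(res & ON_TARGET_MUTATIONS)
        amplified = "EGFR_amp" in res
        if on:
            hypo_f = float(rng.uniform(0.20, 0.55))
            cna_f = float(np.clip(0.8 * hypo_f + rng.normal(0, 0.02), 0.01, 1.0))
            # TTTR loads on the (standardized) CNA burden with slope rho
            x = (cna_f - 0.30) / 0.11
            tttr = float(
                np.maximum(300 + 150 * (rho * x + resid * rng.normal()), 30)
            )
            pconf = simulate.PatientSimConfig(
                patient_id=pid,
                group="on_target",
                hypo_fraction_true=hypo_f,
                cna_fraction_true=cna_f,
                amplification_true=float(rng.uniform(1.5, 3.0))
                if amplified else 1.0,
                amp_gene_bins=tuple(int(b) for b in amp_bins)
                if amplified else (),
                tttr_days=tttr,
            )
        else:
            pconf = simulate.PatientSimConfig(
                patient_id=pid,
                group="off_target",
                tttr_days=float(np.maximum(rng.normal(300, 150), 30)),
            )
        designs.append((pconf, res))
    return designs


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate a cohort and run every analysis stage over it.

    Returns a result bundle (baseline, per-sample summaries, DMR table,
    cohort statistics, patient records, manifest) and, when ``out_dir``
    is given, writes all tables as TSV/JSON plus a run manifest.  A
    fixed seed makes outputs byte-identical across runs.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config,
            simulation=dataclasses.replace(config.simulation, seed=seed),
        )
    results: dict = {}
    stage = "generate"
    try:
        if config.input_dir is not None:
            stage = "load"
            data = _load_cohort(Path(config.input_dir))
        else:
            data = _simulate_cohort(config)
        bins = data.bins
        healthy, patients, designs = data.healthy, data.patients, data.designs

        stage = "baseline"
        md_h = np.stack(
            [methylome.methylation_density(s.meth_c, s.total_c) for s in healthy]
        )
        norm_h = np.stack(
            [
                cna_mod.process_counts(s.sample_id, s.read_count, bins)
                .normalized_count
                for s in healthy
            ]
        )
        baseline = genome.fit_baseline(md_h, norm_h, bins)

        stage = "methylome"
        meth_summaries = []
        for s in patients:
            prof = methylome.BinProfile(
                sample_id=s.sample_id, bins=bins,
                meth_c=s.meth_c, total_c=s.total_c,
            )
            prof = methylome.call_hypomethylated(
                prof, baseline, sd_multiplier=config.sd_multiplier
            )
            meth_summaries.append(methylome.summarize_methylome(prof))

        stage = "cna"
        cna_summaries = []
        amp_scores = {}
        for s, (pconf, _res) in zip(patients, designs):
            prof = cna_mod.process_counts(
                s.sample_id, s.read_count, bins,
                baseline=baseline, z_cut=config.z_cut,
            )
            cna_summaries.append(cna_mod.summarize_cna(prof))
            if pconf.amp_gene_bins:
                amp_scores[s.sample_id] = cna_mod.amplification_score(
                    prof, pconf.amp_gene_bins, baseline, gene="EGFR"
                )

        stage = "panel_dmr"
        pct = panel.pct_matrix_from_counts(data.panel_tidy)
        groups = pd.Series({s.sample_id: s.group for s in patients})
        dmr = panel.call_dmrs(pct, groups, "on_target", "off_target")

        stage = "stats"
        records = []
        for s, (pconf, res), msum, csum in zip(
            patients, designs, meth_summaries, cna_summaries
        ):
            amp = amp_scores.get(s.sample_id)
            records.append(
                PatientRecord(
                    patient_id=s.sample_id,
                    sensitizing="del19",
                    resistance=res or frozenset({"T790M"}),
                    amplification_score=amp.score if amp else float("nan"),
                    tttr_days=pconf.tttr_days,
                    hypo_fraction=msum.hypo_fraction,
                    cna_fraction=csum.cna_fraction,
                )
            )
        rec_frame = pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in records],
                "group": [r.group for r in records],
                "hypo_fraction": [r.hypo_fraction for r in records],
                "cna_fraction": [r.cna_fraction for r in records],
                "amplification_score": [r.amplification_score for r in records],
                "tttr_days": [r.tttr_days for r in records],
            }
        )
        on = rec_frame[rec_frame.group == "on_target"]
        off = rec_frame[rec_frame.group == "off_target"]
        stats_out = {
            "mann_whitney_hypo_p": mann_whitney(
                on.hypo_fraction, off.hypo_fraction
            ),
            "mann_whitney_cna_p": mann_whitney(
                on.cna_fraction, off.cna_fraction
            ),
            "on_target_mean_hypo_fraction": float(on.hypo_fraction.mean()),
            "off_target_mean_hypo_fraction": float(off.hypo_fraction.mean()),
            "hypo_cna_pearson": pearson_with_ci(
                rec_frame.hypo_fraction, rec_frame.cna_fraction
            ),
        }
        egfr_amp = rec_frame[
            [("EGFR_amp" in r.resistance) for r in records]
        ]
        if len(egfr_amp) >= 3:
            stats_out["tttr_cna_pearson"] = pearson_with_ci(
                egfr_amp.cna_fraction, egfr_amp.tttr_days
            )
            stats_out["tttr_hypo_pearson"] = pearson_with_ci(
                egfr_amp.hypo_fraction, egfr_amp.tttr_days
            )
            stats_out["tttr_amp_pearson"] = pearson_with_ci(
                egfr_amp.amplification_score, egfr_amp.tttr_days
            )

        results = {
            "bins": bins,
            "baseline": baseline,
            "methylome_summaries": meth_summaries,
            "cna_summaries": cna_summaries,
            "amplification_scores": amp_scores,
            "pct_matrix": pct,
            "dmr": dmr,
            "records": records,
            "record_frame": rec_frame,
            "stats": stats_out,
            "truth": data.truth,
            "manifest": {
                "seed": config.simulation.seed,
                "n_bins": len(bins),
                "n_healthy": len(healthy),
                "n_patients": len(patients),
                "sd_multiplier": config.sd_multiplier,
                "z_cut": config.z_cut,
                "panel": dataclasses.asdict(config.panel),
                "stages": [
                    "generate", "baseline", "methylome",
                    "cna", "panel_dmr", "stats",
                ],
            },
        }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        _write_pipeline_outputs(results, Path(out_dir))
    return results


def _corr_to_dict(c: CorrelationResult) -> dict:
    return dataclasses.asdict(c)


def _write_pipeline_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    genome.write_baseline_tsv(results["baseline"], out_dir / "baseline.tsv")
    genome.write_registry_bed(results["bins"], out_dir / "bins.bed")
    pd.DataFrame([dataclasses.asdict(m) for m in results["methylome_summaries"]]).to_csv(
        out_dir / "methylome_summary.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    pd.DataFrame([dataclasses.asdict(c) for c in results["cna_summaries"]]).to_csv(
        out_dir / "cna_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )
    results["dmr"].to_csv(
        out_dir / "dmr_results.tsv", sep="\t", index=False, float_format="%.10g"
    )
    results["pct_matrix"].to_csv(
        out_dir / "panel_pct_matrix.tsv", sep="\t", float_format="%.10g"
    )
    results["record_frame"].to_csv(
        out_dir / "sample_sheet.tsv", sep="\t", index=False, float_format="%.10g"
    )
    stats_json = {
        k: (_corr_to_dict(v) if isinstance(v, CorrelationResult) else v)
        for k, v in results["stats"].items()
    }
    (out_dir / "cohort_stats.json").write_text(
        json.dumps(stats_json, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "truth.json").write_text(
        json.dumps(results["truth"], indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# calibration and recovery experiments
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int,
    n_reference: int = 400,
    n_samples: int = 200,
    chrom_lengths: dict | None = None,
) -> dict:
    """Mean hypo-bin and CNA-bin fraction of unperturbed samples.

    With a large reference cohort the plug-in threshold mean - 3 SD
    approaches the true 0.135th percentile, so the expected hypo-bin
    fraction approaches Phi(-3) ~= 0.00135 and the two-sided CNA-bin
    fraction 2 Phi(-3) ~= 0.0027.  (At the study's reference size of 20
    the same quantity is a Student-t tail, ~0.0043 one-sided; the large
    ``n_reference`` default isolates the calibration of the calling rule
    itself from reference-estimation noise.)
    """
    cfg = simulate.SimulationConfig(
        seed=seed,
        n_healthy=n_reference,
        chrom_lengths=chrom_lengths or simulate.SMALL_CHROM_LENGTHS,
    )
    sim = simulate.CohortSimulator(cfg)
    reference = sim.healthy(n_reference)
    md_h = np.stack(
        [methylome.methylation_density(s.meth_c, s.total_c) for s in reference]
    )
    norm_h = np.stack(
        [
            cna_mod.process_counts(s.sample_id, s.read_count, sim.bins)
            .normalized_count
            for s in reference
        ]
    )
    baseline = genome.fit_baseline(md_h, norm_h, sim.bins)

    hypo_fracs, cna_fracs = [], []
    for s in sim.healthy(n_samples):
        prof = methylome.call_hypomethylated(
            methylome.BinProfile(
                sample_id=s.sample_id, bins=sim.bins,
                meth_c=s.meth_c, total_c=s.total_c,
            ),
            baseline,
        )
        hypo_fracs.append(methylome.summarize_methylome(prof).hypo_fraction)
        cprof = cna_mod.process_counts(
            s.sample_id, s.read_count, sim.bins, baseline=baseline
        )
        cna_fracs.append(cna_mod.summarize_cna(cprof).cna_fraction)
    return {
        "mean_hypo_fraction": float(np.mean(hypo_fracs)),
        "mean_cna_fraction": float(np.mean(cna_fracs)),
        "n_samples": n_samples,
        "n_reference": n_reference,
    }


def recovery_experiment(
    seed: int,
    fractions: Sequence[float] = (0.05, 0.20, 0.39),
    hypo_effect_sds: float = 8.0,
    cna_effect_sds: float = 6.0,
) -> dict:
    """Recover generator hypo/CNA bin fractions through the full pipeline.

    Study-scale reference (20 healthy subjects), one patient per target
    fraction, large effects so detection is limited by calling logic
    rather than power.
    """
    cfg = simulate.SimulationConfig(
        seed=seed, chrom_lengths=simulate.SMALL_CHROM_LENGTHS
    )
    sim = simulate.CohortSimulator(cfg)
    reference = sim.healthy()
    md_h = np.stack(
        [methylome.methylation_density(s.meth_c, s.total_c) for s in reference]
    )
    norm_h = np.stack(
        [
            cna_mod.process_counts(s.sample_id, s.read_count, sim.bins)
            .normalized_count
            for s in reference
        ]
    )
    baseline = genome.fit_baseline(md_h, norm_h, sim.bins)

    out = {}
    for f in fractions:
        pconf = simulate.PatientSimConfig(
            patient_id=f"rec-{f:.2f}",
            group="on_target",
            hypo_fraction_true=f,
            hypo_effect_sds=hypo_effect_sds,
            cna_fraction_true=f,
            cna_effect_sds=cna_effect_sds,
        )
        s = sim.patient(pconf)
        prof = methylome.call_hypomethylated(
            methylome.BinProfile(
                sample_id=s.sample_id, bins=sim.bins,
                meth_c=s.meth_c, total_c=s.total_c,
            ),
            baseline,
        )
        cprof = cna_mod.process_counts(
            s.sample_id, s.read_count, sim.bins, baseline=baseline
        )
        out[f] = {
            "hypo_estimate": methylome.summarize_methylome(prof).hypo_fraction,
            "cna_estimate": cna_mod.summarize_cna(cprof).cna_fraction,
        }
    return out


def dmr_recovery_experiment(
    seed: int,
    n_reps: int = 20,
    n_on: int = 11,
    n_off: int = 8,
    pcfg: simulate.PanelSimConfig | None = None,
) -> dict:
    """DMR recall and false-call rate over replicated panel cohorts."""
    pcfg = pcfg or simulate.PanelSimConfig()
    recalls, false_rates = [], []
    first_counts = None
    for rep in range(n_reps):
        cfg = simulate.SimulationConfig(
            seed=seed + rep, chrom_lengths={"chr1": 2_000_000}
        )
        sim = simulate.CohortSimulator(cfg)
        rows = []
        groups = {}
        for i in range(n_on + n_off):
            group = "on_target" if i < n_on else "off_target"
            sid = f"S{i + 1:02d}"
            groups[sid] = group
            meth, unmeth, truth = sim.panel(group, pcfg)
            rows.extend(
                {
                    "sample": sid,
                    "region_id": f"region_{j + 1:04d}",
                    "meth_c": int(m),
                    "unmeth_c": int(u),
                }
                for j, (m, u) in enumerate(zip(meth, unmeth))
            )
        pct = panel.pct_matrix_from_counts(pd.DataFrame(rows))
        dmr = panel.call_dmrs(pct, groups, "on_target", "off_target")
        dmr = dmr.set_index("region_id")
        hyper_ids = [f"region_{j + 1:04d}" for j in truth["hyper_regions"]]
        hypo_ids = [f"region_{j + 1:04d}" for j in truth["hypo_regions"]]
        null_ids = [
            r for r in dmr.index if r not in set(hyper_ids) | set(hypo_ids)
        ]
        correct = (dmr.loc[hyper_ids, "call"] == "hyper").sum() + (
            dmr.loc[hypo_ids, "call"] == "hypo"
        ).sum()
        recalls.append(correct / (len(hyper_ids) + len(hypo_ids)))
        false_rates.append((dmr.loc[null_ids, "call"] != "none").mean())
        if first_counts is None:
            first_counts = {
                "hyper_calls": int((dmr["call"] == "hyper").sum()),
                "hypo_calls": int((dmr["call"] == "hypo").sum()),
            }
    return {
        "mean_recall": float(np.mean(recalls)),
        "mean_false_call_rate": float(np.mean(false_rates)),
        "n_reps": n_reps,
        **first_counts,
    }


def umi_suppression_experiment(
    seed: int,
    n_families: int = 10_000,
    family_size: int = 3,
    error_rate: float = 0.05,
    read_length: int = 20,
) -> dict:
    """Per-base error before vs after UMI consensus over many families."""
    cfg = simulate.SimulationConfig(seed=seed, chrom_lengths={"chr1": 1_000_000})
    sim = simulate.CohortSimulator(cfg)
    families, truths = sim.umi_families(
        n_families, family_size, read_length=read_length, error_rate=error_rate
    )
    raw_errors = raw_bases = 0
    cons_errors = n_calls = total_positions = 0
    for fam, truth in zip(families, truths):
        for read in fam.reads:
            raw_bases += len(read)
            raw_errors += sum(a != b for a, b in zip(read, truth))
        frag = umi.consensus(fam)
        total_positions += len(truth)
        for a, b in zip(frag.consensus, truth):
            if a == "N":
                n_calls += 1
            elif a != b:
                cons_errors += 1
    return {
        "raw_error_rate": raw_errors / raw_bases,
        "consensus_error_rate": cons_errors / total_positions,
        "no_call_rate": n_calls / total_positions,
        "n_families": n_families,
        "family_size": family_size,
    }
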