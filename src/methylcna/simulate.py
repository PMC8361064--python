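"""Synthetic cfDNA cohort generator.

Emulates the data the analysis consumes, at the statistical level the
pipeline assumes, so every downstream stage is testable without
sequencing data: a healthy reference cohort of per-bin methylation
densities and read counts with a smooth GC bias; patients whose genomes
carry genome-wide hypomethylation and segmental copy-number aberrations
(on-target EGFR-driven resistance) or look like healthy plasma
(off-target bypass amplification); a 450-region promoter panel with
hyper- and hypo-methylated regions in the on-target group; UMI read
families with injected per-base errors; and clinical covariates (time to
treatment resistance, amplification scores) with a configurable
correlation structure.

Counts are negative-binomial (configurable dispersion) so robustness to
over-dispersion is testable; per-bin methylation probabilities are
truncated-normal around the cohort baseline; the GC bias is a smooth
quadratic that the LOESS corrector is expected to remove.  A fixed seed
makes every output byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (
    DEFAULT_BIN_SIZE,
    HG38_AUTOSOME_LENGTHS,
    GenomicBin,
    build_bin_registry,
)
from .panel import PanelRegion
from .umi import UmiFamily

__all__ = [
    "SimulationConfig",
    "PatientSimConfig",
    "PanelSimConfig",
    "SyntheticSample",
    "CohortSimulator",
    "simulate_healthy",
    "simulate_patient",
    "simulate_panel",
    "simulate_umi_families",
    "simulate_clinical",
]

#: Small synthetic genome (22 autosomes x 46 Mb = 1012 bins) for
#: calibration experiments where only the per-bin law matters.
SMALL_CHROM_LENGTHS: dict[str, int] = {
    f"chr{i}": 46_000_000 for i in range(1, 23)
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults mirror the study conditions: a 20-subject healthy
    reference; low-pass bisulfite sequencing of ~20 M reads per sample
    (~0.6x), i.e. about 7,000 reads and 12,000 CpG observations per
    1 Mb autosomal bin; healthy methylation density around 0.70 with
    per-subject per-bin SD 0.03.
    """

    seed: int = 0
    n_healthy: int = 20
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(HG38_AUTOSOME_LENGTHS)
    )
    bin_size: int = DEFAULT_BIN_SIZE
    md_baseline_mean: float = 0.70
    md_baseline_sd: float = 0.03
    coverage_mean: float = 7_000.0
    cpg_obs_mean: float = 12_000.0
    gc_mean: float = 0.42
    gc_sd: float = 0.05
    gc_bias_strength: float = 0.5
    nb_dispersion: float = 0.002
    cna_segment_mean_bins: float = 20.0

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0 or self.cpg_obs_mean <= 0:
            raise ValueError("coverage_mean and cpg_obs_mean must be positive")
        if not (0.0 <= self.md_baseline_mean <= 1.0):
            raise ValueError("md_baseline_mean must lie in [0, 1]")
        if self.md_baseline_sd < 0:
            raise ValueError("md_baseline_sd must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.n_healthy < 2:
            raise ValueError("n_healthy must be at least 2")


@dataclass(frozen=True)
class PatientSimConfig:
    """Per-patient perturbation settings."""

    patient_id: str
    group: str  # "on_target" | "off_target"
    hypo_fraction_true: float = 0.0
    hypo_effect_sds: float = 8.0
    cna_fraction_true: float = 0.0
    cna_effect_sds: float = 6.0
    #: fraction of CNA bins that are also hypomethylated bins
    overlap: float = 0.8
    contiguous_cna: bool = True
    #: >1 multiplies read counts over ``amp_gene_bins`` (proxy for a
    #: focal gene amplification, e.g. EGFR)
    amplification_true: float = 1.0
    amp_gene_bins: tuple[int, ...] = ()
    tttr_days: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in ("on_target", "off_target"):
            raise ValueError(f"unknown patient group {self.group!r}")
        for name in ("hypo_fraction_true", "cna_fraction_true", "overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hypo_fraction_true > 0 and self.hypo_effect_sds <= 0:
            raise ValueError("hypo_effect_sds must be positive")
        if self.cna_fraction_true > 0 and self.cna_effect_sds <= 0:
            raise ValueError("cna_effect_sds must be positive")
        if self.amplification_true <= 0:
            raise ValueError("amplification_true must be positive")


@dataclass(frozen=True)
class PanelSimConfig:
    """450-region methylation panel with a 202 hyper / 58 hypo contrast.

    Hyper-target regions start lowly methylated (CpG-island promoters)
    and gain methylation in on-target patients; hypo-target regions
    start fully methylated and lose it; the remaining regions are null.
    """

    n_regions: int = 450
    n_hyper: int = 202
    n_hypo: int = 58
    base_hyper: float = 0.2
    base_hypo: float = 0.8
    effect: float = 0.6  # additive shift in methylation probability
    cpg_obs_per_region: float = 200.0

    def __post_init__(self) -> None:
        if self.n_hyper + self.n_hypo > self.n_regions:
            raise ValueError("shifted regions exceed panel size")
        if self.cpg_obs_per_region < 0:
            raise ValueError("cpg_obs_per_region must be non-negative")


@dataclass
class SyntheticSample:
    """One simulated sample's count tables plus its generating truth."""

    sample_id: str
    group: str
    meth_c: np.ndarray
    total_c: np.ndarray
    read_count: np.ndarray
    panel_meth_c: np.ndarray | None = None
    panel_unmeth_c: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.meth_c > self.total_c):
            raise AssertionError("meth_c exceeds total_c")
        for arr in (self.meth_c, self.total_c, self.read_count):
            if np.any(np.asarray(arr) < 0):
                raise AssertionError("negative counts")


def _gc_bias_curve(gc: np.ndarray, strength: float) -> np.ndarray:
    """Smooth quadratic coverage bias in GC fraction, strictly positive."""
    u = gc - 0.45
    return np.maximum(1.0 + strength * (u - 4.0 * u**2), 0.1)


class CohortSimulator:
    """Holds one reproducible simulation context: registry, GC, RNG.

    All samples drawn from one simulator share the same bin registry and
    GC fractions, as a sequencing cohort shares one genome.
    """

    def __init__(self, config: SimulationConfig, seed: int | None = None):
        self.config = config
        self.rng = np.random.default_rng(config.seed if seed is None else seed)
        base_bins = build_bin_registry(config.chrom_lengths, config.bin_size)
        gc = np.clip(
            self.rng.normal(config.gc_mean, config.gc_sd, len(base_bins)),
            0.25, 0.65,
        )
        self.bins: list[GenomicBin] = [
            GenomicBin(b.chrom, b.start, b.end, float(g))
            for b, g in zip(base_bins, gc)
        ]
        self.gc = gc
        bias = _gc_bias_curve(gc, config.gc_bias_strength)
        self._bias = bias / bias.mean()

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    # ---- count primitives -------------------------------------------------

    def _counts(self, mean: np.ndarray) -> np.ndarray:
        """Negative-binomial counts (Poisson when dispersion is 0)."""
        alpha = self.config.nb_dispersion
        mean = np.maximum(mean, 1e-9)
        if alpha == 0:
            return self.rng.poisson(mean)
        size = 1.0 / alpha
        lam = self.rng.gamma(shape=size, scale=mean / size)
        return self.rng.poisson(lam)

    def _raw_count_sd(self, mean: np.ndarray) -> np.ndarray:
        alpha = self.config.nb_dispersion
        return np.sqrt(mean + alpha * mean**2)

    def _draw_bins(
        self, p_mean: np.ndarray, count_mean: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cfg = self.config
        p = np.clip(
            self.rng.normal(p_mean, cfg.md_baseline_sd), 0.0, 1.0
        )
        total_c = self._counts(cfg.cpg_obs_mean * self._bias)
        meth_c = self.rng.binomial(total_c, p)
        read_count = self._counts(count_mean)
        return meth_c, total_c, read_count

    # ---- samples ----------------------------------------------------------

    def healthy(self, n: int | None = None) -> list[SyntheticSample]:
        cfg = self.config
        n = cfg.n_healthy if n is None else n
        samples = []
        p_mean = np.full(self.n_bins, cfg.md_baseline_mean)
        count_mean = cfg.coverage_mean * self._bias
        for i in range(n):
            meth_c, total_c, read_count = self._draw_bins(p_mean, count_mean)
            samples.append(
                SyntheticSample(
                    sample_id=f"H{i + 1:03d}",
                    group="healthy",
                    meth_c=meth_c,
                    total_c=total_c,
                    read_count=read_count,
                    truth={"hypo_bins": [], "cna_bins": []},
                )
            )
        return samples

    def _cna_segments(self, n_target: int, exclude: set[int]) -> list[int]:
        """Contiguous segments (geometric lengths) totalling n_target bins."""
        chosen: list[int] = []
        taken = set(exclude)
        mean_len = max(self.config.cna_segment_mean_bins, 1.0)
        guard = 0
        while len(chosen) < n_target and guard < 10_000:
            guard += 1
            start = int(self.rng.integers(0, self.n_bins))
            length = int(self.rng.geometric(1.0 / mean_len))
            seg = [
                i for i in range(start, min(start + length, self.n_bins))
                if i not in taken
            ]
            seg = seg[: n_target - len(chosen)]
            chosen.extend(seg)
            taken.update(seg)
        return sorted(chosen)

    def patient(self, pconf: PatientSimConfig) -> SyntheticSample:
        cfg = self.config
        n = self.n_bins
        truth: dict = {
            "patient_id": pconf.patient_id,
            "group": pconf.group,
            "hypo_bins": [],
            "cna_bins": [],
            "cna_signs": {},
            "amp_bins": list(pconf.amp_gene_bins),
        }
        p_mean = np.full(n, cfg.md_baseline_mean)
        count_mean = cfg.coverage_mean * self._bias.copy()

        if pconf.group == "on_target":
            n_cna = int(round(pconf.cna_fraction_true * n))
            n_hypo = int(round(pconf.hypo_fraction_true * n))
            # CNA bins first (contiguous segments), then the hypo set is
            # built to contain `overlap` of the CNA bins.
            if pconf.contiguous_cna:
                cna_bins = self._cna_segments(n_cna, exclude=set())
            else:
                cna_bins = sorted(
                    self.rng.choice(n, size=n_cna, replace=False).tolist()
                )
            n_shared = min(int(round(pconf.overlap * n_cna)), n_hypo, n_cna)
            shared = (
                sorted(
                    self.rng.choice(cna_bins, size=n_shared, replace=False).tolist()
                )
                if n_shared
                else []
            )
            pool = np.setdiff1d(np.arange(n), np.asarray(cna_bins, dtype=int))
            n_rest = n_hypo - n_shared
            rest = (
                sorted(self.rng.choice(pool, size=n_rest, replace=False).tolist())
                if n_rest
                else []
            )
            hypo_bins = sorted(shared + rest)

            if hypo_bins:
                p_mean[hypo_bins] = np.clip(
                    cfg.md_baseline_mean
                    - pconf.hypo_effect_sds * cfg.md_baseline_sd,
                    0.0, 1.0,
                )
            if cna_bins:
                sd = self._raw_count_sd(count_mean[cna_bins])
                # one sign per contiguous run of CNA bins
                runs = np.split(
                    np.asarray(cna_bins),
                    np.where(np.diff(cna_bins) != 1)[0] + 1,
                )
                for run in runs:
                    sign = 1.0 if self.rng.random() < 0.5 else -1.0
                    idx = run.astype(int)
                    pos = np.searchsorted(cna_bins, idx)
                    shift = sign * pconf.cna_effect_sds * sd[pos]
                    count_mean[idx] = np.maximum(
                        count_mean[idx] + shift, 0.05 * count_mean[idx]
                    )
                    for i in idx:
                        truth["cna_signs"][int(i)] = int(sign)
            truth["hypo_bins"] = hypo_bins
            truth["cna_bins"] = cna_bins

        if pconf.amplification_true != 1.0 and pconf.amp_gene_bins:
            idx = np.asarray(pconf.amp_gene_bins, dtype=int)
            count_mean[idx] *= pconf.amplification_true

        meth_c, total_c, read_count = self._draw_bins(p_mean, count_mean)
        return SyntheticSample(
            sample_id=pconf.patient_id,
            group=pconf.group,
            meth_c=meth_c,
            total_c=total_c,
            read_count=read_count,
            truth=truth,
        )

    # ---- panel ------------------------------------------------------------

    def panel_regions(self, pcfg: PanelSimConfig) -> list[PanelRegion]:
        regions = []
        for i in range(pcfg.n_regions):
            chrom = f"chr{i % 22 + 1}"
            start = 100_000 + 10_000 * (i // 22)
            regions.append(
                PanelRegion(
                    region_id=f"region_{i + 1:04d}",
                    gene=f"GENE{i + 1}",
                    chrom=chrom,
                    start=start,
                    end=start + 1_000,
                    n_cpg=20,
                )
            )
        return regions

    def panel_base_probs(self, pcfg: PanelSimConfig) -> np.ndarray:
        """Healthy/off-target methylation probability per region."""
        probs = np.empty(pcfg.n_regions)
        probs[: pcfg.n_hyper] = pcfg.base_hyper
        probs[pcfg.n_hyper : pcfg.n_hyper + pcfg.n_hypo] = pcfg.base_hypo
        n_null = pcfg.n_regions - pcfg.n_hyper - pcfg.n_hypo
        probs[pcfg.n_hyper + pcfg.n_hypo :] = np.linspace(0.1, 0.9, n_null)
        return probs

    def panel(
        self, group: str, pcfg: PanelSimConfig
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Per-region (meth_c, unmeth_c) counts for one sample."""
        if pcfg.n_regions < 1:
            raise ValueError("panel must contain at least 1 region")
        probs = self.panel_base_probs(pcfg)
        truth = {
            "hyper_regions": list(range(pcfg.n_hyper)),
            "hypo_regions": list(
                range(pcfg.n_hyper, pcfg.n_hyper + pcfg.n_hypo)
            ),
            "clamped_regions": [],
        }
        if group == "on_target":
            raw = probs.copy()
            raw[: pcfg.n_hyper] += pcfg.effect
            raw[pcfg.n_hyper : pcfg.n_hyper + pcfg.n_hypo] -= pcfg.effect
            clamped = np.where((raw < 0) | (raw > 1))[0]
            if clamped.size:
                truth["clamped_regions"] = clamped.tolist()
            probs = np.clip(raw, 0.0, 1.0)
        n_obs = self.rng.poisson(pcfg.cpg_obs_per_region, pcfg.n_regions)
        meth = self.rng.binomial(n_obs, probs)
        return meth, n_obs - meth, truth

    # ---- UMI families -----------------------------------------------------

    def umi_families(
        self,
        n_families: int,
        family_size: int,
        read_length: int = 20,
        error_rate: float = 0.0,
        alt_fraction: float = 0.0,
        locus: int = 0,
        ref: str = "A",
        alt: str = "T",
    ) -> tuple[list[UmiFamily], list[str]]:
        """Simulated read families with known truth sequences.

        Each family derives from one truth fragment; per-base errors are
        injected independently at ``error_rate`` (substituting a uniform
        different base).  ``alt_fraction`` of truth fragments carry
        ``alt`` instead of ``ref`` at ``locus``.
        """
        if not (0.0 <= error_rate < 0.5):
            raise ValueError(
                "error_rate must lie in [0, 0.5); the >50% consensus rule "
                "cannot suppress errors at or above 0.5"
            )
        if family_size < 1 or n_families < 1:
            raise ValueError("n_families and family_size must be positive")
        bases = np.array(list("ACGT"))
        truth_idx = self.rng.integers(0, 4, size=(n_families, read_length))
        ref_i, alt_i = "ACGT".index(ref), "ACGT".index(alt)
        truth_idx[:, locus] = ref_i
        if alt_fraction > 0:
            n_alt = int(round(alt_fraction * n_families))
            carriers = self.rng.choice(n_families, size=n_alt, replace=False)
            truth_idx[carriers, locus] = alt_i
        reads_idx = np.repeat(truth_idx[:, None, :], family_size, axis=1)
        if error_rate > 0:
            err = self.rng.random(reads_idx.shape) < error_rate
            # substitute a uniformly random *different* base
            offset = self.rng.integers(1, 4, size=reads_idx.shape)
            reads_idx = np.where(err, (reads_idx + offset) % 4, reads_idx)
        umi_width = len(str(n_families))
        families = []
        truths = []
        for f in range(n_families):
            umi = f"UMI{f:0{umi_width}d}"
            reads = tuple(
                "".join(bases[reads_idx[f, r]]) for r in range(family_size)
            )
            families.append(UmiFamily(umi=umi, reads=reads))
            truths.append("".join(bases[truth_idx[f]]))
        return families, truths

    # ---- clinical covariates ----------------------------------------------

    def clinical(
        self,
        n: int,
        rho: float,
        tttr_mean: float = 300.0,
        tttr_sd: float = 120.0,
    ) -> pd.DataFrame:
        """Joint model coupling TTTR with genome-instability read-outs.

        A latent standard normal drives TTTR; CNA fraction,
        hypomethylation fraction and amplification score each load on it
        with coefficient ``rho``, so every pairwise correlation with
        TTTR is ``rho`` in expectation (before range clipping).
        """
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"target correlation must lie in (-1, 1), got {rho}")
        if n < 1:
            raise ValueError("n must be positive")
        z = self.rng.normal(size=n)
        resid = np.sqrt(1 - rho**2)

        def coupled() -> np.ndarray:
            return rho * z + resid * self.rng.normal(size=n)

        return pd.DataFrame(
            {
                "patient_id": [f"P{i + 1:03d}" for i in range(n)],
                "tttr_days": np.maximum(tttr_mean + tttr_sd * z, 1.0),
                "cna_fraction": np.clip(0.30 + 0.08 * coupled(), 0.0, 1.0),
                "hypo_fraction": np.clip(0.35 + 0.10 * coupled(), 0.0, 1.0),
                "amplification_score": np.maximum(2.0 + 0.4 * coupled(), 1.0),
            }
        )


# ---- functional wrappers ---------------------------------------------------

def simulate_healthy(config: SimulationConfig) -> list[SyntheticSample]:
    """Healthy reference cohort under ``config`` (fresh simulator)."""
    return CohortSimulator(config).healthy()


def simulate_patient(
    config: SimulationConfig, pconf: PatientSimConfig
) -> SyntheticSample:
    return CohortSimulator(config).patient(pconf)


def simulate_panel(
    config: SimulationConfig, group: str, pcfg: PanelSimConfig | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    return CohortSimulator(config).panel(group, pcfg or PanelSimConfig())


def simulate_umi_families(
    config: SimulationConfig, n_families: int, family_size: int, **kwargs
) -> tuple[list[UmiFamily], list[str]]:
    return CohortSimulator(config).umi_families(n_families, family_size, **kwargs)


def simulate_clinical(
    config: SimulationConfig, n: int, rho: float, **kwargs
) -> pd.DataFrame:
    return CohortSimulator(config).clinical(n, rho, **kwargs)
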