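import statistics

import numpy as np
import pytest

from methylcna import cna, genome


class TestGcCorrect:
    def test_counts_independent_of_gc_left_nearly_unchanged(self, rng):
        gc = rng.uniform(0.3, 0.6, 1000)
        raw = rng.poisson(5000, 1000).astype(float)
        corrected = cna.gc_correct(raw, gc)
        rel = np.abs(corrected / raw - 1)
        assert rel.max() < 0.02

    def test_exact_smooth_bias_removed(self, rng):
        gc = rng.uniform(0.3, 0.6, 1000)
        bias = 1 + 0.5 * (gc - 0.45) - 2.0 * (gc - 0.45) ** 2
        raw = 5000 * bias  # noise-free smooth bias
        corrected = cna.gc_correct(raw, gc)
        assert np.abs(corrected / corrected.mean() - 1).max() < 0.03

    def test_single_gc_stratum_is_identity_with_warning(self):
        raw = np.array([10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="identical"):
            out = cna.gc_correct(raw, np.full(3, 0.4))
        np.testing.assert_array_equal(out, raw)

    def test_mean_correction_factor_is_one(self, rng):
        gc = rng.uniform(0.3, 0.6, 500)
        raw = rng.poisson(3000, 500) * (1 + 0.8 * (gc - 0.45))
        corrected = cna.gc_correct(raw, gc)
        factor = corrected / raw
        assert factor.mean() == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cna.gc_correct(np.array([-1.0, 2.0]), np.array([0.4, 0.5]))


class TestMedianNormalize:
    def test_constant_counts_become_one(self):
        np.testing.assert_array_equal(
            cna.median_normalize(np.full(5, 500.0)), np.ones(5)
        )

    def test_small_example(self):
        np.testing.assert_allclose(
            cna.median_normalize([1.0, 2.0, 3.0]), [0.5, 1.0, 1.5]
        )

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 100, 50)
        np.testing.assert_allclose(
            cna.median_normalize(x), cna.median_normalize(10 * x)
        )

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            cna.median_normalize(np.zeros(4))


class TestZScores:
    def test_at_mean_zero_and_boundary_not_flagged(self, toy_baseline):
        toy_baseline.count_sd[0] = 0.25  # exact binary fraction
        x = toy_baseline.count_mean.copy()
        x[0] = 1.75  # exactly mean + 3 SD
        prof = cna.CnaProfile(
            sample_id="S", bins=toy_baseline.bins,
            raw_count=x, normalized_count=x,
        )
        prof = cna.call_cna(prof, toy_baseline)
        assert prof.z[1] == 0.0
        assert prof.z[0] == pytest.approx(3.0)
        assert prof.cna_flag[0] == 0.0  # strict inequality at |z| = 3

    def test_z_missing_where_non_evaluable(self, toy_baseline):
        toy_baseline.evaluable[2] = False
        x = toy_baseline.count_mean.copy()
        z = cna.cna_zscores(x, toy_baseline)
        assert np.isnan(z[2])

    def test_large_segment_all_flagged(self, toy_baseline):
        x = toy_baseline.count_mean.copy()
        x[10:20] += 5 * toy_baseline.count_sd[10:20]
        prof = cna.CnaProfile(
            sample_id="S", bins=toy_baseline.bins,
            raw_count=x, normalized_count=x,
        )
        prof = cna.call_cna(prof, toy_baseline)
        assert np.all(prof.cna_flag[10:20] == 1.0)
        assert np.nansum(prof.cna_flag) == 10

    def test_summary_fraction(self, toy_baseline):
        x = toy_baseline.count_mean.copy()
        x[:5] -= 4 * toy_baseline.count_sd[:5]
        prof = cna.call_cna(
            cna.CnaProfile(
                sample_id="S", bins=toy_baseline.bins,
                raw_count=x, normalized_count=x,
            ),
            toy_baseline,
        )
        s = cna.summarize_cna(prof)
        assert s.n_cna_bins == 5
        assert s.cna_fraction == pytest.approx(5 / len(toy_baseline.bins))


class TestBruteForceOracle:
    def test_small_bin_pipeline_matches_independent_arithmetic(self, rng):
        # 20 bins, 4 GC strata -> stratum-median GC correction; the
        # oracle recomputes correct -> normalize -> z with python loops.
        bins = genome.build_bin_registry({"chr1": 20_000_000})
        gc_values = [0.35, 0.40, 0.45, 0.50]
        gc = np.array([gc_values[i % 4] for i in range(20)])
        bins = [
            genome.GenomicBin(b.chrom, b.start, b.end, g)
            for b, g in zip(bins, gc)
        ]
        raw = rng.uniform(500, 1500, 20)
        base = genome.ReferenceBaseline(
            n_subjects=5, bins=bins,
            md_mean=np.full(20, 0.7), md_sd=np.full(20, 0.05),
            count_mean=np.full(20, 1.0), count_sd=np.full(20, 0.08),
            evaluable=np.ones(20, dtype=bool),
        )
        prof = cna.process_counts("S", raw, bins, baseline=base)

        # oracle: stratum medians, mean-1 rescale, median division, z
        fhat = []
        for x, g in zip(raw, gc):
            stratum = [r for r, gg in zip(raw, gc) if gg == g]
            fhat.append(statistics.median(stratum))
        factors = [1.0 / f for f in fhat]
        mean_factor = sum(factors) / len(factors)
        corrected = [x * f / mean_factor for x, f in zip(raw, factors)]
        med = statistics.median(corrected)
        normalized = [c / med for c in corrected]
        z = [(v - 1.0) / 0.08 for v in normalized]
        np.testing.assert_allclose(prof.corrected_count, corrected)
        np.testing.assert_allclose(prof.normalized_count, normalized)
        np.testing.assert_allclose(prof.z, z, atol=1e-9)
        for zi, flag in zip(z, prof.cna_flag):
            assert flag == (1.0 if abs(zi) > 3 else 0.0)

    def test_bin_permutation_permutes_outputs(self, rng):
        gc = rng.uniform(0.3, 0.6, 200)
        raw = rng.poisson(2000, 200).astype(float)
        corrected = cna.gc_correct(raw, gc)
        perm = rng.permutation(200)
        corrected_perm = cna.gc_correct(raw[perm], gc[perm])
        np.testing.assert_allclose(corrected_perm, corrected[perm], rtol=1e-9)


class TestAmplificationScore:
    def _setup(self, toy_baseline, factor):
        x = toy_baseline.count_mean.copy()
        gene = [7, 8, 9]
        x[gene] *= factor
        prof = cna.CnaProfile(
            sample_id="S", bins=toy_baseline.bins,
            raw_count=x, normalized_count=x,
        )
        return prof, gene

    def test_unamplified_score_is_one(self, toy_baseline):
        prof, gene = self._setup(toy_baseline, 1.0)
        s = cna.amplification_score(prof, gene, toy_baseline, gene="EGFR")
        assert s.score == pytest.approx(1.0)
        assert s.gene == "EGFR"

    def test_doubled_bins_score_two(self, toy_baseline):
        prof, gene = self._setup(toy_baseline, 2.0)
        s = cna.amplification_score(prof, gene, toy_baseline)
        assert s.score == pytest.approx(2.0)
        assert s.n_bins == 3

    def test_empty_gene_bins_rejected(self, toy_baseline):
        prof, _ = self._setup(toy_baseline, 1.0)
        with pytest.raises(ValueError, match="empty"):
            cna.amplification_score(prof, [], toy_baseline)

    def test_no_evaluable_gene_bin_rejected(self, toy_baseline):
        prof, gene = self._setup(toy_baseline, 1.0)
        toy_baseline.evaluable[gene] = False
        with pytest.raises(ValueError, match="no evaluable"):
            cna.amplification_score(prof, gene, toy_baseline)
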