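import numpy as np
import pytest

from methylcna import genome, methylome


class TestMethylationDensity:
    @pytest.mark.parametrize(
        "meth, total, expected",
        [(50, 100, 0.5), (0, 100, 0.0), (100, 100, 1.0)],
    )
    def test_examples(self, meth, total, expected):
        assert methylome.methylation_density(meth, total) == expected

    def test_below_min_cpg_obs_is_missing(self):
        assert np.isnan(methylome.methylation_density(3, 5, min_cpg_obs=10))

    def test_meth_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            methylome.methylation_density(6, 5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            methylome.methylation_density(-1, 5)

    def test_vectorized(self):
        md = methylome.methylation_density([5, 50, 3], [10, 100, 5])
        np.testing.assert_allclose(md[:2], [0.5, 0.5])
        assert np.isnan(md[2])


def _profile(bins, md_values, min_obs=10):
    """Build a profile whose densities equal md_values exactly."""
    total = np.full(len(bins), 1000)
    meth = np.round(np.asarray(md_values) * total).astype(int)
    return methylome.BinProfile(
        sample_id="S1", bins=list(bins), meth_c=meth, total_c=total,
        min_cpg_obs=min_obs,
    )


class TestHypomethylationCalls:
    def test_strictly_below_threshold_is_hypo(self, toy_baseline):
        # baseline mean 0.70, sd 0.05 -> threshold 0.55
        md = np.full(len(toy_baseline.bins), 0.70)
        md[0] = 0.54
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, md), toy_baseline
        )
        assert prof.hypo_flag[0] == 1.0
        assert np.nansum(prof.hypo_flag) == 1

    def test_boundary_exactly_at_threshold_not_hypo(self, toy_baseline):
        md = np.full(len(toy_baseline.bins), 0.70)
        md[0] = 0.55
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, md), toy_baseline
        )
        assert prof.hypo_flag[0] == 0.0

    def test_sample_at_baseline_mean_has_zero_hypo(self, toy_baseline):
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, np.full(len(toy_baseline.bins), 0.70)),
            toy_baseline,
        )
        assert np.nansum(prof.hypo_flag) == 0

    def test_missing_md_and_non_evaluable_bins_get_missing_flag(
        self, toy_baseline
    ):
        n = len(toy_baseline.bins)
        toy_baseline.evaluable[5] = False
        prof = _profile(toy_baseline.bins, np.full(n, 0.4))
        prof.total_c[3] = 5  # below min_cpg_obs
        prof = methylome.BinProfile(
            sample_id="S1", bins=toy_baseline.bins,
            meth_c=np.minimum(prof.meth_c, prof.total_c),
            total_c=prof.total_c,
        )
        called = methylome.call_hypomethylated(prof, toy_baseline)
        assert np.isnan(called.hypo_flag[3])
        assert np.isnan(called.hypo_flag[5])

    def test_registry_mismatch_rejected(self, toy_baseline):
        other = genome.build_bin_registry({"chr1": 50_000_000})
        prof = _profile(other, np.full(len(other), 0.7))
        with pytest.raises(ValueError, match="diverge"):
            methylome.call_hypomethylated(prof, toy_baseline)

    def test_raising_multiplier_never_increases_calls(self, toy_baseline, rng):
        md = rng.uniform(0.4, 0.8, len(toy_baseline.bins))
        prof = _profile(toy_baseline.bins, md)
        counts = [
            np.nansum(
                methylome.call_hypomethylated(
                    prof, toy_baseline, sd_multiplier=k
                ).hypo_flag
            )
            for k in (1, 2, 3, 4, 5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_brute_force_oracle_agreement(self, toy_baseline, rng):
        # independent re-computation with plain python arithmetic
        md = rng.uniform(0.4, 0.9, len(toy_baseline.bins))
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, md), toy_baseline
        )
        recomputed_md = prof.meth_c / prof.total_c
        for i in range(len(toy_baseline.bins)):
            expected = (
                1.0
                if recomputed_md[i]
                < toy_baseline.md_mean[i] - 3 * toy_baseline.md_sd[i]
                else 0.0
            )
            assert prof.hypo_flag[i] == expected


class TestMethylomeSummary:
    def test_zero_hypo(self, toy_baseline):
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, np.full(len(toy_baseline.bins), 0.7)),
            toy_baseline,
        )
        s = methylome.summarize_methylome(prof)
        assert s.hypo_fraction == 0.0
        assert s.n_evaluable_bins == len(toy_baseline.bins)

    def test_fraction_matches_counts(self):
        # 1000 evaluable bins, 389 hypomethylated -> 38.9%
        bins = genome.build_bin_registry({"chr1": 1_000_000_000})
        assert len(bins) == 1000
        base = genome.ReferenceBaseline(
            n_subjects=20, bins=bins,
            md_mean=np.full(1000, 0.7), md_sd=np.full(1000, 0.05),
            count_mean=np.ones(1000), count_sd=np.full(1000, 0.1),
            evaluable=np.ones(1000, dtype=bool),
        )
        md = np.full(1000, 0.7)
        md[:389] = 0.3
        prof = methylome.call_hypomethylated(_profile(bins, md), base)
        s = methylome.summarize_methylome(prof)
        assert s.n_hypo_bins == 389
        assert s.hypo_fraction == pytest.approx(0.389)

    def test_fraction_excludes_non_evaluable_bins(self, toy_baseline):
        toy_baseline.evaluable[:10] = False
        md = np.full(len(toy_baseline.bins), 0.7)
        md[:20] = 0.3  # 10 of these fall on non-evaluable bins
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, md), toy_baseline
        )
        s = methylome.summarize_methylome(prof)
        assert s.n_evaluable_bins == len(toy_baseline.bins) - 10
        assert s.n_hypo_bins == 10

    def test_zero_evaluable_bins_rejected(self, toy_baseline):
        toy_baseline.evaluable[:] = False
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, np.full(len(toy_baseline.bins), 0.7)),
            toy_baseline,
        )
        with pytest.raises(ValueError, match="zero evaluable"):
            methylome.summarize_methylome(prof)

    def test_requires_populated_flags(self, toy_baseline):
        prof = _profile(toy_baseline.bins, np.full(len(toy_baseline.bins), 0.7))
        with pytest.raises(ValueError, match="hypo_flag"):
            methylome.summarize_methylome(prof)

    def test_fraction_invariant_to_bin_order(self, toy_baseline, rng):
        md = rng.uniform(0.4, 0.9, len(toy_baseline.bins))
        prof = methylome.call_hypomethylated(
            _profile(toy_baseline.bins, md), toy_baseline
        )
        s1 = methylome.summarize_methylome(prof)
        perm = rng.permutation(len(toy_baseline.bins))
        shuffled = methylome.BinProfile(
            sample_id="S1",
            bins=[toy_baseline.bins[i] for i in perm],
            meth_c=prof.meth_c[perm], total_c=prof.total_c[perm],
            hypo_flag=prof.hypo_flag[perm],
        )
        s2 = methylome.summarize_methylome(shuffled)
        assert s1.hypo_fraction == s2.hypo_fraction
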