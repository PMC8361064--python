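from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylcna import panel

from .oracles import bh_step_up, exact_rank_sum_p


class TestRegionMethylation:
    @pytest.mark.parametrize(
        "meth, unmeth, expected",
        [(30, 70, 30.0), (0, 50, 0.0), (50, 0, 100.0)],
    )
    def test_examples(self, meth, unmeth, expected):
        assert panel.region_methylation(meth, unmeth) == expected

    def test_zero_coverage_is_missing(self):
        assert np.isnan(panel.region_methylation(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            panel.region_methylation(-1, 5)


class TestWilcoxonRankSum:
    def test_identical_groups_p_near_one(self):
        assert panel.wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) >= 0.99

    def test_complete_separation_exact_p(self):
        a = list(range(100, 110))  # n1 = 10, all larger
        b = list(range(10, 18))    # n2 = 8
        p = panel.wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(2 / comb(18, 8), rel=1e-12)

    @pytest.mark.parametrize("case_seed", range(8))
    def test_matches_full_enumeration_small_n(self, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, min(7, 14 - n1)))
        values = rng.permutation(100)[: n1 + n2].astype(float)
        a, b = values[:n1], values[n1:]
        assert panel.wilcoxon_rank_sum(a, b) == pytest.approx(
            exact_rank_sum_p(a, b), abs=1e-12
        )

    def test_type_i_error_calibrated(self):
        # exchangeable null, exact path (8 vs 8, continuous data)
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            x = rng.normal(size=16)
            if panel.wilcoxon_rank_sum(x[:8], x[8:]) <= 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            panel.wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert panel.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            panel.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(panel.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            panel.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=30,
        )
    )
    def test_matches_textbook_recursion_and_dominates_p(self, p_values):
        q = panel.bh_adjust(p_values)
        np.testing.assert_allclose(q, bh_step_up(p_values), atol=1e-12)
        assert np.all(q >= np.asarray(p_values) - 1e-12)
        assert np.all(q <= 1.0)


def _pct_matrix(rng, n_a=6, n_b=6, n_regions=30, shift=None):
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    groups = pd.Series(
        ["on"] * n_a + ["off"] * n_b, index=samples
    )
    data = rng.uniform(30, 50, size=(n_a + n_b, n_regions))
    if shift is not None:
        for region, delta in shift.items():
            data[:n_a, region] += delta
    pct = pd.DataFrame(
        np.clip(data, 0, 100),
        index=samples,
        columns=[f"r{j:03d}" for j in range(n_regions)],
    )
    return pct, groups


class TestCallDmrs:
    def test_label_swap_negates_log2fc_and_swaps_calls(self, rng):
        pct, groups = _pct_matrix(rng, shift={0: 60, 1: -35})
        fwd = panel.call_dmrs(pct, groups, "on", "off")
        rev = panel.call_dmrs(pct, groups, "off", "on")
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, atol=1e-12)
        np.testing.assert_allclose(fwd.p, rev.p)
        np.testing.assert_allclose(fwd.q, rev.q)
        swap = {"hyper": "hypo", "hypo": "hyper", "none": "none"}
        assert [swap[c] for c in fwd.call] == list(rev.call)

    def test_exact_log2fc_boundary_not_called(self):
        # group means 41 and 20 -> log2((41+1)/(20+1)) = 1 exactly
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        groups = pd.Series(["on"] * 4 + ["off"] * 4, index=samples)
        pct = pd.DataFrame(
            {"r0": [40.0, 40.5, 41.5, 42.0, 19.0, 19.5, 20.5, 21.0]},
            index=samples,
        )
        res = panel.call_dmrs(pct, groups, "on", "off")
        assert res.log2fc[0] == pytest.approx(1.0)
        assert res.q[0] < 0.05  # complete separation, single region
        assert res.call[0] == "none"

    def test_null_regions_produce_almost_no_calls(self):
        calls = 0
        for seed in range(3):
            rng = np.random.default_rng(7000 + seed)
            pct, groups = _pct_matrix(rng, n_a=8, n_b=8, n_regions=450)
            res = panel.call_dmrs(pct, groups, "on", "off")
            calls += (res.call != "none").sum()
        assert calls <= 5

    def test_poorly_covered_region_excluded_and_reported(self, rng):
        pct, groups = _pct_matrix(rng, n_a=4, n_b=4, n_regions=5)
        pct.iloc[:3, 0] = np.nan  # 3 of 4 group-A samples missing
        res = panel.call_dmrs(pct, groups, "on", "off")
        row = res.set_index("region_id").loc["r000"]
        assert not row.tested
        assert row.reason == "insufficient coverage"
        assert np.isnan(row.q)
        # q-values computed across tested regions only
        assert res.q.notna().sum() == 4

    def test_empty_group_rejected(self, rng):
        pct, groups = _pct_matrix(rng)
        with pytest.raises(ValueError, match=">=2 samples"):
            panel.call_dmrs(pct, groups, "on", "missing_group")

    def test_strong_shifts_recovered_with_direction(self, rng):
        shift = {j: 50.0 for j in range(5)} | {j: -25.0 for j in range(5, 8)}
        pct, groups = _pct_matrix(
            rng, n_a=11, n_b=8, n_regions=40, shift=shift
        )
        res = panel.call_dmrs(pct, groups, "on", "off").set_index("region_id")
        assert all(res.loc[f"r{j:03d}", "call"] == "hyper" for j in range(5))
        assert all(res.loc[f"r{j:03d}", "call"] == "hypo" for j in range(5, 8))

    def test_q_monotone_in_sorted_p_order(self, rng):
        pct, groups = _pct_matrix(rng, n_regions=60)
        res = panel.call_dmrs(pct, groups, "on", "off")
        tested = res[res.tested].sort_values("p")
        assert np.all(np.diff(tested.q) >= -1e-12)


class TestPctMatrix:
    def test_pivot_and_missing(self):
        counts = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s2", "s2"],
                "region_id": ["r1", "r2", "r1", "r2"],
                "meth_c": [30, 0, 10, 5],
                "unmeth_c": [70, 0, 90, 5],
            }
        )
        pct = panel.pct_matrix_from_counts(counts)
        assert pct.loc["s1", "r1"] == 30.0
        assert np.isnan(pct.loc["s1", "r2"])  # zero coverage -> missing
        assert pct.loc["s2", "r2"] == 50.0
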