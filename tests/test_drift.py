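"""Stratification, trajectories, drift rates, inter-age regression, and
fold-change histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redrift import (
    BinFrame,
    drift_rate,
    foldchange_histogram,
    methylome_regression,
    scale_stratum_sizes,
    stratify_by_baseline,
    stratum_test,
    stratum_trajectory,
)
from redrift.bin_quant import NormalizedMethylome


def methylome_from(values_by_sample: dict) -> NormalizedMethylome:
    samples = list(values_by_sample)
    arr = np.column_stack([np.asarray(values_by_sample[s], float) for s in samples])
    frame = BinFrame({"c1": 500 * arr.shape[0]}, 500)
    return NormalizedMethylome(frame, arr, samples, "fpkm")


class TestStratify:
    base = methylome_from({"m2": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]})

    def test_top_ranked_high(self):
        s = stratify_by_baseline(self.base, "m2", 2, 2, 3, mid_target_level=5.5)
        assert set(s["high"].bin_indices) == {8, 9}

    def test_bottom_ranked_low(self):
        s = stratify_by_baseline(self.base, "m2", 2, 2, 3, mid_target_level=5.5)
        assert set(s["low"].bin_indices) == {0, 1, 2}

    def test_mid_nearest_to_target(self):
        s = stratify_by_baseline(self.base, "m2", 2, 2, 3, mid_target_level=5.5)
        assert set(s["mid"].bin_indices) == {4, 5}  # values 5 and 6

    def test_strata_are_disjoint(self):
        s = stratify_by_baseline(self.base, "m2", 3, 3, 4, mid_target_level=5.5)
        all_idx = np.concatenate([st.bin_indices for st in s.values()])
        assert len(all_idx) == len(set(all_idx)) == 10

    def test_fully_tied_values_still_partition_deterministically(self):
        tied = methylome_from({"m2": [5, 5, 5, 5, 5]})
        s = stratify_by_baseline(tied, "m2", 2, 1, 2, mid_target_level=5)
        assert s["high"].bin_indices.tolist() == [0, 1]
        assert s["low"].bin_indices.tolist() == [3, 4]
        assert s["mid"].bin_indices.tolist() == [2]

    def test_oversized_request_fatal(self):
        with pytest.raises(ValueError, match="exceed"):
            stratify_by_baseline(self.base, "m2", 6, 2, 5, mid_target_level=5)

    def test_default_sizes_scale_proportionally(self):
        h, m, l = scale_stratum_sizes(20_000)
        assert h + m + l == 20_000
        assert h == m
        # keeps the genome-scale high:low ratio to within rounding
        assert l / h == pytest.approx(1_048_575 / 100_000, rel=0.01)
        assert scale_stratum_sizes(3_000_000) == (100_000, 100_000, 1_048_575)


class TestTrajectory:
    def test_identical_samples_give_zero_everywhere(self):
        v = [1.0, 5.0, 9.0, 2.0]
        m = methylome_from({"m2": v, "m20": v, "m28": v})
        strata = stratify_by_baseline(m, "m2", 1, 1, 1, mid_target_level=5.0)
        for t in stratum_trajectory(m, strata, "m2", ["m20", "m28"]):
            np.testing.assert_array_equal(t.mean_log2_fc, 0.0)

    def test_baseline_entry_exactly_zero(self):
        m = methylome_from({"m2": [1, 2, 3, 4], "m28": [4, 3, 2, 1]})
        strata = stratify_by_baseline(m, "m2", 1, 1, 1, mid_target_level=2.5)
        for t in stratum_trajectory(m, strata, "m2", ["m28"]):
            assert t.mean_log2_fc[0] == 0.0 and t.sd_log2_fc[0] == 0.0

    def test_fold_magnitude_and_rate_use_paper_convention(self):
        # mean log2 FC of -0.4646 corresponds to a 1.38-fold reduction
        v2 = np.array([100.0, 200.0, 300.0, 400.0])
        v28 = (v2 + 1) / 2**0.4646 - 1
        m = methylome_from({"m2": v2, "m28": v28})
        strata = stratify_by_baseline(m, "m2", 1, 1, 1, mid_target_level=100.0)
        (t, *_) = stratum_trajectory(
            m, strata, "m2", ["m28"], months={"m28": 20}
        )
        assert t.fold_magnitude[1] == pytest.approx(1.38, abs=1e-3)
        assert t.direction[1] == -1
        assert t.rate_per_month[1] == pytest.approx(0.069, abs=1e-3)

    def test_empty_stratum_fatal(self):
        from redrift import DriftStratum

        m = methylome_from({"m2": [1, 2], "m28": [1, 2]})
        with pytest.raises(ValueError, match="empty"):
            stratum_trajectory(m, [DriftStratum("high", [], 0)], "m2", ["m28"])


class TestDriftRate:
    def test_paper_worked_examples(self):
        assert drift_rate(1.38, 20) == pytest.approx(0.069)
        assert drift_rate(2.6, 28) == pytest.approx(0.0929, abs=5e-5)
        assert drift_rate(0, 12) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0, 100, allow_nan=False),
        st.floats(0.1, 100, allow_nan=False),
        st.floats(0.1, 10, allow_nan=False),
    )
    def test_linear_in_fold_and_inverse_in_months(self, fold, months, a):
        assert drift_rate(a * fold, months) == pytest.approx(a * drift_rate(fold, months))
        assert drift_rate(fold, a * months) == pytest.approx(drift_rate(fold, months) / a)

    def test_nonpositive_months_fatal(self):
        with pytest.raises(ValueError):
            drift_rate(1.38, 0)


class TestRegression:
    def test_exact_identity_line(self):
        m = methylome_from({"x": [1, 2, 3, 4], "y": [1, 2, 3, 4]})
        r = methylome_regression(m, "x", "y")
        assert r.slope == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.pearson_r == pytest.approx(1.0)

    def test_exact_affine_line_on_log_scale(self):
        x = np.array([1.0, 3.0, 7.0, 15.0])  # log2(x+1) = 1,2,3,4
        y = 2.0 ** (0.5 * np.log2(x + 1) + 1) - 1  # log2(y+1) = 0.5 log2(x+1) + 1
        m = methylome_from({"x": x, "y": y})
        r = methylome_regression(m, "x", "y")
        assert r.slope == pytest.approx(0.5)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_r_squared_equals_r_squared_of_pearson(self, rng):
        m = methylome_from({"x": rng.random(50) * 10, "y": rng.random(50) * 10})
        r = methylome_regression(m, "x", "y")
        assert r.r_squared == pytest.approx(r.pearson_r**2, abs=1e-9)

    def test_zero_variance_fatal(self):
        m = methylome_from({"x": [2, 2, 2], "y": [1, 2, 3]})
        with pytest.raises(ValueError, match="variance"):
            methylome_regression(m, "x", "y")


class TestStratumTest:
    def test_identical_groups(self):
        t, p = stratum_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_constant_equal_groups_convention(self):
        assert stratum_test([2, 2, 2], [2, 2]) == (0.0, 1.0)

    def test_power_at_unit_separation(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        _, p = stratum_test(a, b)
        assert p < 1e-10

    def test_swap_negates_t_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1.2, 60)
        t1, p1 = stratum_test(a, b)
        t2, p2 = stratum_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestFoldChangeHistogram:
    def test_identical_samples_mass_at_zero_interval(self):
        v = [1.0, 2.0, 3.0]
        m = methylome_from({"a": v, "b": v})
        h = foldchange_histogram(m, "a", "b", edges=[-1, -0.01, 0.01, 1])
        assert h.counts.tolist() == [0, 3, 0]
        assert h.underflow == h.overflow == 0

    def test_counts_conserved_under_edge_refinement(self, rng):
        a = rng.random(200) * 10
        b = rng.random(200) * 10
        m = methylome_from({"a": a, "b": b})
        coarse = foldchange_histogram(m, "a", "b", edges=np.linspace(-4, 4, 5))
        fine = foldchange_histogram(m, "a", "b", edges=np.linspace(-4, 4, 41))
        assert coarse.total == fine.total == 200
        assert coarse.counts.sum() == fine.counts.sum()

    def test_out_of_range_values_counted_in_overflow(self):
        m = methylome_from({"a": [1.0, 1.0], "b": [1000.0, 1.0]})
        h = foldchange_histogram(m, "a", "b", edges=[-1, 1])
        assert h.overflow == 1 and h.counts.sum() == 1

    def test_too_few_edges_fatal(self):
        m = methylome_from({"a": [1.0], "b": [1.0]})
        with pytest.raises(ValueError):
            foldchange_histogram(m, "a", "b", edges=[0])
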