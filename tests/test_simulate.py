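"""The generative model: placement, planted templates, drift law, read model,
and expression trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redrift import (
    AgingSimSpec,
    BinFrame,
    GenomicInterval,
    RepeatCopy,
    apply_aging_drift,
    generate_baseline_methylome,
    generate_repeat_annotation,
    simulate_expression_counts,
    simulate_mbd_reads,
)


def line1_only_spec(n=1000, mixture=(0.8, 0.15, 0.05), seed=0):
    return AgingSimSpec(
        n_copies_per_family={"LINE1": n},
        length_distribution={"LINE1": mixture},
        seed=seed,
    )


class TestAnnotation:
    def test_copies_do_not_overlap_and_stay_in_bounds(self):
        spec = AgingSimSpec(seed=3)
        copies, _ = generate_repeat_annotation(spec)
        by_chrom = {}
        for c in copies:
            by_chrom.setdefault(c.chrom, []).append(c)
        for chrom, cs in by_chrom.items():
            cs = sorted(cs, key=lambda c: c.start)
            assert cs[-1].end <= spec.chrom_lengths[chrom]
            assert all(a.end <= b.start for a, b in zip(cs, cs[1:]))

    def test_zero_copies_gives_background_only_cpgs(self):
        spec = AgingSimSpec(
            n_copies_per_family={f: 0 for f in AgingSimSpec().n_copies_per_family}
        )
        copies, cpgs = generate_repeat_annotation(spec)
        assert copies == []
        assert all(len(v) > 0 for v in cpgs.values())  # background rate > 0

    def test_long_fraction_matches_mixture_within_binomial_ci(self):
        copies, _ = generate_repeat_annotation(line1_only_spec())
        frac = np.mean([c.length > 5000 for c in copies])
        # 3 sigma binomial band around p = 0.05 at n = 1000
        assert 0.029 < frac < 0.071

    def test_fixed_seed_reproducible(self):
        spec = AgingSimSpec(seed=11)
        a, cpg_a = generate_repeat_annotation(spec)
        b, cpg_b = generate_repeat_annotation(spec)
        assert [(c.copy_id, c.start, c.strand) for c in a] == [
            (c.copy_id, c.start, c.strand) for c in b
        ]
        assert all(np.array_equal(cpg_a[k], cpg_b[k]) for k in cpg_a)

    def test_placement_failure_is_fatal_with_advice(self):
        spec = AgingSimSpec(
            chrom_lengths={"tiny": 10_000},
            n_copies_per_family={"LINE1": 500},
            length_distribution={"LINE1": (0.0, 0.0, 1.0)},
        )
        with pytest.raises(RuntimeError, match="enlarge"):
            generate_repeat_annotation(spec)


class TestBaselineMethylome:
    @pytest.fixture()
    def two_copy_setup(self):
        spec = AgingSimSpec(
            chrom_lengths={"c1": 20_000},
            plateau_jitter=(1.0, 1.0),
            seed=5,
        )
        copies = [
            RepeatCopy(GenomicInterval("c1", 5_000, 10_000, "+"), "ERVK", "IAPEz-int", "a"),
            RepeatCopy(GenomicInterval("c1", 10_000, 15_000, "-"), "ERVK", "IAPEz-int", "b"),
        ]
        meth, truth = generate_baseline_methylome(spec, copies)
        return spec, meth, truth

    def test_ervk_template_peaks_at_both_ends_5p_stronger(self, two_copy_setup):
        spec, meth, truth = two_copy_setup
        assert truth.cluster == {"a": 1, "b": 1}  # round(0.2 * 2) = 0 low copies
        body = meth[10:20]  # bins of copy "a"
        assert body[0] > body[5]  # 5' peak above the plateau
        assert body[-1] > body[5]  # 3' peak above the plateau
        assert body[0] > body[-1]  # 5' peak is the stronger

    def test_minus_strand_profile_is_reverse_of_plus(self, two_copy_setup):
        spec, meth, truth = two_copy_setup
        plus = meth[10:20]
        minus = meth[20:30]
        np.testing.assert_allclose(minus, plus[::-1], rtol=1e-12)

    def test_all_low_cluster_scales_global_copy_signal(self):
        spec = AgingSimSpec(
            chrom_lengths={"c1": 20_000},
            plateau_jitter=(1.0, 1.0),
            cluster2_fraction=0.999999,
            seed=5,
        )
        copies = [
            RepeatCopy(GenomicInterval("c1", 5_000, 10_000, "+"), "ERVK", "IAPEz-int", "a"),
        ]
        meth, truth = generate_baseline_methylome(spec, copies)
        assert truth.cluster["a"] == 2
        tpl_mean = float(np.mean(spec.family_templates["ERVK"]))
        body_mean = meth[10:20].mean()
        assert body_mean == pytest.approx(spec.plateau_low * tpl_mean, rel=0.05)

    def test_stratum_labels_partition_all_bins(self, default_study):
        stratum = default_study.truth.stratum
        labels, counts = np.unique(stratum, return_counts=True)
        assert set(labels) == {"high", "mid", "low"}
        assert counts.sum() == default_study.frame.n_bins


class TestDrift:
    def test_zero_months_and_disabled_tissue_are_identity(self):
        spec = AgingSimSpec()
        m = np.array([0.9, 0.1, 0.5, 0.5])
        np.testing.assert_array_equal(apply_aging_drift(m, 0, spec, "muscle"), m)
        np.testing.assert_array_equal(apply_aging_drift(m, 26, spec, "tcell"), m)

    def test_loss_closed_form(self):
        spec = AgingSimSpec(drift_rate_loss=0.005, drift_rate_gain=0.01)
        m = np.array([0.9, 0.1, 0.5, 0.5])  # mean exactly 0.5
        out = apply_aging_drift(m, 20, spec, "muscle")
        assert out[0] == pytest.approx(0.8141, abs=2e-4)  # 0.9 * 0.995**20
        assert out[1] == pytest.approx(0.1 + 0.4 * (1 - 0.99**20), rel=1e-12)
        assert out[2] == 0.5 and out[3] == 0.5

    def test_negative_months_fatal(self):
        with pytest.raises(ValueError):
            apply_aging_drift(np.array([0.5]), -1, AgingSimSpec(), "muscle")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=30),
        st.integers(0, 40),
        st.integers(1, 20),
    )
    def test_regression_toward_mean_and_monotonicity(self, values, months, extra):
        spec = AgingSimSpec()
        m = np.asarray(values)
        mean = m.mean()
        out1 = apply_aging_drift(m, months, spec, "muscle")
        out2 = apply_aging_drift(m, months + extra, spec, "muscle")
        assert np.all(np.abs(out1 - mean) <= np.abs(m - mean) + 1e-12)
        assert np.all(np.abs(out2 - mean) <= np.abs(out1 - mean) + 1e-12)
        assert np.all((out1 >= 0) & (out1 <= 1))


class TestMbdReads:
    frame = BinFrame({"c1": 1000}, 500)

    def test_zero_methylation_bin_gets_zero_reads(self):
        reads = simulate_mbd_reads(
            np.array([0.0, 0.5]), np.array([10, 10]), self.frame, 1000, 50.0, seed=0
        )
        assert np.all(reads.starts >= 500)

    def test_expected_counts_follow_methylation_ratio(self):
        reads = simulate_mbd_reads(
            np.array([0.8, 0.2]), np.array([10, 10]), self.frame, 10_000, 1000.0, seed=1
        )
        n0 = int(np.sum(reads.starts < 500))
        n1 = len(reads) - n0
        # mu = (8000, 2000); 3 NB sigma ~= 360 at size 1000
        assert abs(n0 - 8000) < 360
        assert abs(n1 - 2000) < 200

    def test_library_size_scaling_in_expectation(self):
        kw = dict(cpg_per_bin=np.array([10, 10]), frame=self.frame, nb_dispersion=1000.0)
        a = simulate_mbd_reads(np.array([0.5, 0.5]), library_size=5_000, seed=2, **kw)
        b = simulate_mbd_reads(np.array([0.5, 0.5]), library_size=10_000, seed=3, **kw)
        assert len(b) / len(a) == pytest.approx(2.0, rel=0.05)

    def test_reads_are_placed_inside_their_bin(self):
        reads = simulate_mbd_reads(
            np.array([0.5, 0.5]), np.array([5, 5]), self.frame, 2000, 100.0, seed=4
        )
        mid = (reads.starts + reads.ends) // 2
        assert np.all((reads.starts >= 0) & (reads.ends <= 1000))
        # a read placed in a bin keeps its midpoint there
        assert np.all((mid // 500) == (reads.starts // 500))

    def test_fixed_seed_identical_reads(self):
        args = (np.array([0.3, 0.7]), np.array([5, 5]), self.frame, 3000, 50.0)
        a = simulate_mbd_reads(*args, seed=9)
        b = simulate_mbd_reads(*args, seed=9)
        assert np.array_equal(a.starts, b.starts) and np.array_equal(a.ends, b.ends)

    def test_all_zero_expectation_fatal(self):
        with pytest.raises(ValueError, match="all-zero"):
            simulate_mbd_reads(
                np.array([0.0, 0.0]), np.array([10, 10]), self.frame, 1000, 50.0, seed=0
            )


class TestExpression:
    def test_closed_form_age_means_and_phases(self):
        spec = AgingSimSpec(
            expression_phase_effects=(-1.0, 1.0),
            expression_late_other_scale=1.0,
            expression_base_sigma=1e-9,
            expression_nb_dispersion=10_000.0,
            n_background_genes=0,
            n_replicates_rnaseq=6,
        )
        copies = [
            RepeatCopy(GenomicInterval("c1", 0, 4000, "+"), "ERVK", "IAPEz-int", "a"),
            RepeatCopy(GenomicInterval("c1", 5000, 5400, "+"), "LINE1", "L1_Mus3", "b"),
        ]
        table, groups, phases = simulate_expression_counts(
            spec, copies, {"a": 1, "b": 1}, seed=0
        )
        means = {
            age: table[[s for s in table if groups[s] == age]].mean(axis=1)
            for age in (2, 20, 28)
        }
        assert means[2]["a"] == pytest.approx(100, rel=0.1)
        assert means[20]["a"] == pytest.approx(50, rel=0.1)
        assert means[28]["a"] == pytest.approx(100, rel=0.1)
        assert phases == {"a": "down_up", "b": "down_up"}

    def test_null_effects_keep_all_features_flat(self):
        spec = AgingSimSpec(expression_phase_effects=(0.0, 0.0), n_background_genes=10)
        copies = [
            RepeatCopy(GenomicInterval("c1", 0, 4000, "+"), "ERVK", "IAPEz-int", "a"),
        ]
        _, _, phases = simulate_expression_counts(spec, copies, {"a": 1}, seed=0)
        assert set(phases.values()) == {"flat"}

    def test_background_genes_are_stable_anchor(self):
        spec = AgingSimSpec(n_background_genes=50)
        copies = [
            RepeatCopy(GenomicInterval("c1", 0, 4000, "+"), "ERVK", "IAPEz-int", "a"),
        ]
        table, groups, phases = simulate_expression_counts(spec, copies, {"a": 1}, seed=1)
        genes = [f for f in table.index if f.startswith("gene_")]
        assert len(genes) == 50
        assert all(phases[g] == "flat" for g in genes)

    def test_determinism_and_age_requirement(self):
        spec = AgingSimSpec()
        copies = [
            RepeatCopy(GenomicInterval("c1", 0, 4000, "+"), "ERVK", "IAPEz-int", "a"),
        ]
        t1, _, _ = simulate_expression_counts(spec, copies, {"a": 1}, seed=2)
        t2, _, _ = simulate_expression_counts(spec, copies, {"a": 1}, seed=2)
        pd.testing.assert_frame_equal(t1, t2)
        with pytest.raises(ValueError, match="three ages"):
            simulate_expression_counts(
                AgingSimSpec(ages_months=(2, 20)), copies, {"a": 1}, seed=0
            )
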