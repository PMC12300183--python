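"""Abundance pipeline: merging, QC, scaling, normalization, moderated-t
permutation FDR, and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from redoxquant import (
    PipelineError,
    ProteinQuantMatrix,
    SimConfig,
    aggregate_psms,
    differential_abundance,
    hierarchical_cluster,
    log2_and_center,
    merge_protein_groups,
    qc_channels,
    scale_channels,
    simulate_ground_truth,
    simulate_tmt_psms,
    tmt11_design,
)
from redoxquant.abundance import (
    balanced_permutations,
    permutation_fdr_threshold,
    _group_stats,
)


def matrix_from(values: dict, index: list[str]) -> ProteinQuantMatrix:
    vals = pd.DataFrame(values, index=index, dtype=float)
    counts = vals.notna().astype(int)
    return ProteinQuantMatrix(vals, counts)


class TestMergeProteinGroups:
    def test_members_summed_into_one_row(self):
        m = matrix_from({"c1": [10, 20, 30, 5]}, ["a", "b", "c", "d"])
        out = merge_protein_groups(m, {"a": "G", "b": "G", "c": "G"})
        assert out.values.loc["G", "c1"] == 60.0
        assert len(out.proteins) == 2
        assert out.merged_groups["G"] == ["a", "b", "c"]

    def test_row_count_drops_by_group_size_minus_one(self):
        n = 30
        ids = [f"p{i}" for i in range(n)]
        m = matrix_from({"c1": np.arange(n, dtype=float)}, ids)
        group = {pid: "LHCII" for pid in ids[:18]}
        out = merge_protein_groups(m, group)
        assert len(out.proteins) == n - 17

    def test_missing_member_cell_treated_as_zero_when_any_present(self):
        m = matrix_from({"c1": [10.0, np.nan]}, ["a", "b"])
        out = merge_protein_groups(m, {"a": "G", "b": "G"})
        assert out.values.loc["G", "c1"] == 10.0

    def test_all_members_missing_stays_missing(self):
        m = matrix_from({"c1": [np.nan, np.nan], "c2": [1.0, 2.0]}, ["a", "b"])
        out = merge_protein_groups(m, {"a": "G", "b": "G"})
        assert np.isnan(out.values.loc["G", "c1"])

    def test_empty_map_is_identity(self):
        m = matrix_from({"c1": [1.0, 2.0]}, ["a", "b"])
        out = merge_protein_groups(m, {})
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_absent_member_skipped_with_warning(self, caplog):
        m = matrix_from({"c1": [1.0]}, ["a"])
        with caplog.at_level("WARNING"):
            out = merge_protein_groups(m, {"a": "G", "ghost": "G"})
        assert out.values.loc["G", "c1"] == 1.0
        assert any("ghost" in r.message for r in caplog.records)


class TestQcChannels:
    def test_low_total_channel_dropped_by_ratio_rule(self):
        n = 100
        rng = np.random.default_rng(0)
        m = matrix_from({
            "c1": rng.uniform(1, 2, n) * 1e6,
            "c2": rng.uniform(1, 2, n) * 0.9e6,
            "c3": rng.uniform(1, 2, n) * 1.2e6,
            "c4": rng.uniform(1, 2, n) * 5e3,
        }, [f"p{i}" for i in range(n)])
        kept, dropped, report = qc_channels(m, ratio_threshold=100)
        assert dropped == ["c4"]
        row = report.set_index("channel_id").loc["c4"]
        assert row["ratio_to_others"] >= 100

    def test_mostly_missing_channel_dropped(self):
        rng = np.random.default_rng(1)
        n = 100
        vals = {f"c{i}": rng.uniform(1, 2, n) for i in range(3)}
        vals["bad"] = np.where(rng.random(n) < 0.6, np.nan, rng.uniform(1, 2, n))
        m = matrix_from(vals, [f"p{i}" for i in range(n)])
        # make the bad channel's total comparable so only missingness triggers
        m.values["bad"] *= m.values["c0"].sum() / np.nansum(m.values["bad"])
        kept, dropped, _ = qc_channels(m, missing_frac=0.5)
        assert "bad" in dropped

    def test_balanced_channels_all_kept(self):
        rng = np.random.default_rng(2)
        m = matrix_from({f"c{i}": rng.uniform(1, 2, 50) for i in range(4)},
                        [f"p{i}" for i in range(50)])
        kept, dropped, _ = qc_channels(m)
        assert dropped == []
        assert len(kept) == 4

    def test_all_channels_dropped_is_pipeline_error(self):
        m = matrix_from({"c1": [np.nan] * 4 + [1.0],
                         "c2": [np.nan] * 4 + [1.0]},
                        [f"p{i}" for i in range(5)])
        with pytest.raises(PipelineError):
            qc_channels(m, missing_frac=0.5)


class TestScaleChannels:
    def test_two_channel_factors(self):
        m = matrix_from({"c1": [40.0, 60.0], "c2": [120.0, 80.0]}, ["a", "b"])
        out = scale_channels(m)  # totals 100, 200 -> factors 1.5, 0.75
        totals = out.channel_totals()
        assert totals["c1"] == pytest.approx(150.0)
        assert totals["c2"] == pytest.approx(150.0)
        assert out.values.loc["a", "c1"] == pytest.approx(60.0)

    def test_three_channel_grand_mean_target(self):
        m = matrix_from({"c1": [100.0], "c2": [200.0], "c3": [400.0]}, ["a"])
        totals = scale_channels(m).channel_totals()
        np.testing.assert_allclose(totals, 700.0 / 3, rtol=1e-12)

    def test_equal_totals_identity(self):
        m = matrix_from({"c1": [50.0, 50.0], "c2": [60.0, 40.0]}, ["a", "b"])
        out = scale_channels(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent_and_totals_equal_within_1e9(self):
        rng = np.random.default_rng(3)
        m = matrix_from({f"c{i}": rng.lognormal(10, 1, 200) * (i + 1)
                         for i in range(6)}, [f"p{i}" for i in range(200)])
        once = scale_channels(m)
        twice = scale_channels(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)
        totals = once.channel_totals().to_numpy()
        assert np.all(np.abs(totals / totals.mean() - 1) < 1e-9)

    def test_zero_total_channel_rejected(self):
        m = matrix_from({"c1": [0.0], "c2": [1.0]}, ["a"])
        with pytest.raises(PipelineError):
            scale_channels(m)


class TestLog2AndCenter:
    def test_powers_of_two(self):
        m = matrix_from({"c1": [4.0, 8.0, 16.0]}, ["a", "b", "c"])
        out = log2_and_center(m)
        np.testing.assert_allclose(out["c1"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_single_protein_centers_to_zero(self):
        m = matrix_from({"c1": [7.0]}, ["a"])
        assert log2_and_center(m)["c1"].iloc[0] == 0.0

    def test_channel_means_zero_after_centering(self):
        rng = np.random.default_rng(4)
        m = matrix_from({f"c{i}": rng.lognormal(8, 1, 100) for i in range(5)},
                        [f"p{i}" for i in range(100)])
        out = log2_and_center(m)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_zeros_become_missing(self):
        m = matrix_from({"c1": [0.0, 4.0, 8.0]}, ["a", "b", "c"])
        out = log2_and_center(m)
        assert np.isnan(out.loc["a", "c1"])

    def test_median_centering_variant(self):
        m = matrix_from({"c1": [2.0, 4.0, 256.0]}, ["a", "b", "c"])
        out = log2_and_center(m, center="median")
        assert out.loc["b", "c1"] == 0.0


class TestBalancedPermutations:
    def test_even_group_split_in_half(self):
        labels = np.array([True] * 4 + [False] * 5)
        masks = balanced_permutations(labels, 1000, np.random.default_rng(0))
        # C(4,2)*C(5,2) = 60 distinct balanced assignments
        assert len(masks) == 60
        for m in masks:
            assert m.sum() == 4
            assert (m & labels).sum() == 2
        keys = {tuple(np.flatnonzero(m)) for m in masks}
        assert len(keys) == 60  # deduplicated

    def test_odd_group_uses_floor_and_ceil(self):
        labels = np.array([True] * 3 + [False] * 3)
        masks = balanced_permutations(labels, 1000, np.random.default_rng(0))
        ks = {(m & labels).sum() for m in masks}
        assert ks == {1, 2}
        assert len(masks) == 18  # excludes identity and full swap

    def test_subsampling_is_seeded(self):
        labels = np.array([True] * 4 + [False] * 5)
        a = balanced_permutations(labels, 10, np.random.default_rng(5))
        b = balanced_permutations(labels, 10, np.random.default_rng(5))
        assert len(a) == 10
        assert all((x == y).all() for x, y in zip(a, b))


class TestDifferentialAbundance:
    def test_s0_zero_d_equals_plain_t_and_flags_match_exhaustive_oracle(
            self, abundance_design_3v3):
        # tiny matrix, all balanced permutations, independent brute force
        rng = np.random.default_rng(7)
        norm = pd.DataFrame(
            rng.normal(0, 0.1, (2, 6)),
            index=["null_p", "dap_p"],
            columns=abundance_design_3v3.channels,
        )
        norm.loc["dap_p", ["ht1", "ht2", "ht3"]] += 3.0
        res = differential_abundance(norm, abundance_design_3v3, s0=0.0,
                                     target_fdr=0.25, n_perm=10_000, seed=0)
        # d == plain t when s0 = 0
        np.testing.assert_allclose(res.table["d_statistic"],
                                   res.table["t_statistic"], rtol=1e-12)

        # brute-force oracle: enumerate the same balanced permutation set
        # by hand and recompute the FDR curve and flag set from scratch
        X = norm.to_numpy()

        def plain_t(cols1, cols2):
            x1, x2 = X[:, list(cols1)], X[:, list(cols2)]
            n1, n2 = x1.shape[1], x2.shape[1]
            sp2 = ((n1 - 1) * x1.var(1, ddof=1) + (n2 - 1) * x2.var(1, ddof=1)) / (n1 + n2 - 2)
            return (x1.mean(1) - x2.mean(1)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))

        obs = plain_t([0, 1, 2], [3, 4, 5])
        perm_abs = []
        for k in (1, 2):
            for a in itertools.combinations([0, 1, 2], k):
                for b in itertools.combinations([3, 4, 5], 3 - k):
                    g1 = list(a) + list(b)
                    g2 = [i for i in range(6) if i not in g1]
                    perm_abs.append(np.abs(plain_t(g1, g2)))
        perm_abs = np.array(perm_abs)  # (18, 2)
        expected_flags = []
        for c in sorted(np.abs(obs), reverse=True):
            r = int(np.sum(np.abs(obs) >= c))
            v = float(np.mean(np.sum(perm_abs >= c, axis=1)))
            expected_flags.append((c, min(v / r, 1.0)))
        # smallest cutoff with (monotone-smoothed) FDR <= target
        fdrs = [f for _, f in expected_flags]
        smoothed = np.minimum.accumulate(fdrs[::-1])[::-1]
        qualifying = [c for (c, _), s in zip(expected_flags, smoothed) if s <= 0.25]
        cutoff = min(qualifying) if qualifying else np.inf
        oracle_flags = np.abs(obs) >= cutoff
        np.testing.assert_array_equal(res.table["significant"].to_numpy(), oracle_flags)
        assert res.n_permutations == 18

    def test_strong_signal_recovered_with_empirical_fdr_control(self):
        cfg = SimConfig(n_proteins=400, seed=17)
        truth = simulate_ground_truth(cfg)
        psms, design = simulate_tmt_psms(truth, cfg)
        m = aggregate_psms(psms, design)
        kept, dropped, _ = qc_channels(m)
        norm = log2_and_center(scale_channels(m.select_channels(kept)))
        res = differential_abundance(norm, design, seed=17)
        joined = res.table.join(truth.proteins.set_index("protein_id"), how="inner")
        flagged = joined["significant"]
        true_dap = joined["is_dap"]
        assert flagged.sum() > 0
        emp_fdr = (flagged & ~true_dap).sum() / flagged.sum()
        assert emp_fdr <= 0.04
        strong = joined["log2_fc"].abs() >= 2
        assert (flagged & strong).sum() / strong.sum() >= 0.9

    def test_diff_invariant_to_channel_scaling(self, abundance_design_3v3):
        rng = np.random.default_rng(8)
        raw = pd.DataFrame(rng.lognormal(8, 1, (50, 6)),
                           index=[f"p{i}" for i in range(50)],
                           columns=abundance_design_3v3.channels)
        counts = raw.notna().astype(int)
        factors = np.array([1.0, 5.0, 0.2, 3.0, 10.0, 0.5])
        m1 = ProteinQuantMatrix(raw, counts)
        m2 = ProteinQuantMatrix(raw * factors, counts.copy())
        d1 = differential_abundance(log2_and_center(scale_channels(m1)),
                                    abundance_design_3v3, seed=0).table["diff"]
        d2 = differential_abundance(log2_and_center(scale_channels(m2)),
                                    abundance_design_3v3, seed=0).table["diff"]
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_null_p_values_uniform(self):
        # complete data isolates the t machinery: PSM dropout adds a
        # heavy-tailed composition component that the plain t does not model
        # (the moderated d + permutation FDR absorb it downstream)
        cfg = SimConfig(n_proteins=1000, dap_fraction=0.0, seed=23,
                        degenerate_channel=None, missing_rate=0.0)
        truth = simulate_ground_truth(cfg)
        psms, design = simulate_tmt_psms(truth, cfg)
        m = aggregate_psms(psms, design)
        norm = log2_and_center(scale_channels(m))
        res = differential_abundance(norm, design, seed=23)
        p = res.table["p_value"].dropna()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_permutation_machinery_reproducible(self, abundance_design_3v3):
        rng = np.random.default_rng(9)
        norm = pd.DataFrame(rng.normal(size=(30, 6)),
                            index=[f"p{i}" for i in range(30)],
                            columns=abundance_design_3v3.channels)
        r1 = differential_abundance(norm, abundance_design_3v3, seed=4)
        r2 = differential_abundance(norm, abundance_design_3v3, seed=4)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.d_cutoff == r2.d_cutoff


class TestHierarchicalCluster:
    def test_two_strain_partition_recovered(self):
        cfg = SimConfig(n_proteins=300, seed=29)
        truth = simulate_ground_truth(cfg)
        psms, design = simulate_tmt_psms(truth, cfg)
        m = aggregate_psms(psms, design)
        kept, _, _ = qc_channels(m)
        norm = log2_and_center(scale_channels(m.select_channels(kept)))
        sample_cols = [c for c in norm.columns
                       if c in design.channels_for(role="abundance")]
        result = hierarchical_cluster(norm[sample_cols])
        strain_of = dict(zip(design.frame["channel_id"], design.frame["strain"]))
        part = result.col_partition
        clusters_by_strain = {s: {part[c] for c in part.index if strain_of[c] == s}
                              for s in ("HT", "LT")}
        assert clusters_by_strain["HT"].isdisjoint(clusters_by_strain["LT"])

    def test_identical_columns_single_cluster_at_height_zero(self):
        x = np.arange(10, dtype=float)
        norm = pd.DataFrame({"a": x, "b": x, "c": x})
        result = hierarchical_cluster(norm, z_score=False)
        assert (result.col_linkage[:, 2] == 0.0).all()
        assert result.col_partition.nunique() == 1

    def test_z_scored_rows_standardized_and_leaf_order_is_permutation(self):
        rng = np.random.default_rng(10)
        norm = pd.DataFrame(rng.normal(size=(40, 6)),
                            index=[f"p{i}" for i in range(40)],
                            columns=[f"c{i}" for i in range(6)])
        result = hierarchical_cluster(norm)
        np.testing.assert_allclose(result.z_matrix.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(result.z_matrix.std(axis=1, ddof=0), 1.0, rtol=1e-12)
        assert sorted(result.row_order) == sorted(norm.index)
        assert sorted(result.col_order) == sorted(norm.columns)

    def test_constant_rows_dropped_with_warning(self, caplog):
        norm = pd.DataFrame({"a": [1.0, 1.0, 0.0], "b": [1.0, 2.0, 1.0],
                             "c": [1.0, 3.0, 2.0]},
                            index=["flat", "p1", "p2"])
        with caplog.at_level("WARNING"):
            result = hierarchical_cluster(norm)
        assert "flat" not in result.z_matrix.index
        assert result.n_dropped_rows == 1


class TestGroupStats:
    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(0, 1, (20, 4))
        x2 = rng.normal(0.5, 1, (20, 5))
        diff, se, t, p, df, d = _group_stats(x1, x2, s0=0.0)
        ref = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(p, ref.pvalue, rtol=1e-12)
        np.testing.assert_allclose(d, t, rtol=1e-12)

    def test_s0_damps_low_variance_rows(self):
        x1 = np.array([[1.001, 1.002, 1.001]])
        x2 = np.array([[1.101, 1.102, 1.101]])
        *_, d0 = _group_stats(x1, x2, s0=0.0)
        *_, d1 = _group_stats(x1, x2, s0=1.0)
        assert abs(d1[0]) < abs(d0[0])
        assert abs(d1[0]) == pytest.approx(0.1, abs=0.01)
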