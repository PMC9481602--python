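"""AE-MS label-free statistics: filters, imputation, moderated ANOVA, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ubkit.aems import (
    AnovaConfig,
    ImputeConfig,
    LFQMatrix,
    anova_s0,
    bait_correlation,
    deacetylation_fraction,
    impute_missing,
    load_and_filter_lfq,
    prm_normalize,
    profile_and_cluster,
)
from ubkit.errors import PeakFormatError, ValidationError
from ubkit.simulate import LfqSimSpec, simulate_lfq


def _toy_table(values, groups, reverse=None, contaminant=None):
    """Raw-scale MaxQuant-style table from a log2 array."""
    n, _ = values.shape
    table = pd.DataFrame({"Protein IDs": [f"P{i}" for i in range(n)]})
    for j, sample in enumerate(groups):
        col = np.exp2(values[:, j])
        col[np.isnan(values[:, j])] = 0.0
        table[f"LFQ intensity {sample}"] = col
    table["Reverse"] = ["+" if reverse and i in reverse else "" for i in range(n)]
    table["Potential contaminant"] = [
        "+" if contaminant and i in contaminant else "" for i in range(n)
    ]
    return table


class TestLoadAndFilter:
    def _groups(self, baits=("a", "b"), reps=2):
        samples = {f"{b}_{r}": b for b in baits for r in range(reps)}
        return samples

    def test_reverse_and_contaminant_rows_removed(self):
        groups = self._groups()
        values = np.full((5, 4), 25.0)
        table = _toy_table(values, list(groups), reverse={1}, contaminant={3})
        m = load_and_filter_lfq(table, groups, min_valid=2, n_replicates=2)
        assert len(m.values) == 3
        assert "P1" not in m.values.index and "P3" not in m.values.index

    def test_min_valid_filter_drops_sparse_proteins(self):
        baits = ("a",)
        groups = {f"a_{r}": "a" for r in range(8)}
        values = np.full((2, 8), 25.0)
        values[1, :3] = np.nan  # 5 of 8 observed
        table = _toy_table(values, list(groups))
        m = load_and_filter_lfq(table, groups, min_valid=6, n_replicates=8)
        assert list(m.values.index) == ["P0"]

    def test_fully_observed_table_unchanged(self):
        groups = self._groups()
        values = np.random.default_rng(0).normal(25, 1, (7, 4))
        m = load_and_filter_lfq(_toy_table(values, list(groups)), groups, 2, 2)
        assert len(m.values) == 7

    def test_zero_intensity_becomes_missing(self):
        groups = self._groups()
        values = np.full((1, 4), 25.0)
        values[0, 0] = np.nan
        m = load_and_filter_lfq(_toy_table(values, list(groups)), groups, 2, 2)
        assert m.values.iloc[0].isna().sum() == 1

    def test_missing_marker_column_is_format_error(self):
        groups = self._groups()
        table = _toy_table(np.full((2, 4), 25.0), list(groups)).drop(columns=["Reverse"])
        with pytest.raises(PeakFormatError):
            load_and_filter_lfq(table, groups, 2, 2)

    def test_require_all_groups_mode(self):
        groups = {f"{b}_{r}": b for b in ("a", "b") for r in range(4)}
        values = np.full((1, 8), 25.0)
        values[0, :3] = np.nan  # group a: 1 of 4 valid; group b: 4 of 4
        table = _toy_table(values, list(groups))
        any_mode = load_and_filter_lfq(table, groups, min_valid=3, n_replicates=4)
        all_mode = load_and_filter_lfq(
            table, groups, min_valid=3, n_replicates=4, require_all_groups=True
        )
        assert len(any_mode.values) == 1 and len(all_mode.values) == 0


class TestImputation:
    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(25, 2, (50, 4)), columns=list("abcd"))
        values.iloc[:10, 0] = np.nan
        m = LFQMatrix(values, {c: "g" for c in "abcd"})
        out = impute_missing(m, ImputeConfig(seed=0))
        observed = (~values.isna()).to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[observed], values.to_numpy()[observed]
        )
        assert not out.values.isna().any().any()

    def test_no_missing_is_identity(self):
        values = pd.DataFrame(np.random.default_rng(2).normal(25, 2, (20, 3)), columns=list("abc"))
        m = LFQMatrix(values, {c: "g" for c in "abc"})
        out = impute_missing(m, ImputeConfig(seed=0))
        pd.testing.assert_frame_equal(out.values, values)

    def test_downshifted_normal_moments(self):
        # observed column standardized to mean 25, SD 2 exactly; 10,000
        # missing entries should land at Normal(25-1.2*2, (0.3*2)^2)
        rng = np.random.default_rng(3)
        obs = rng.normal(0, 1, 200)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        values = pd.DataFrame({"a": col, "b": np.full(len(col), 25.0)})
        m = LFQMatrix(values, {"a": "g", "b": "g"})
        out = impute_missing(m, ImputeConfig(width=0.3, shift=1.2, seed=7))
        draws = out.values["a"].iloc[200:]
        assert draws.mean() == pytest.approx(25 - 1.2 * 2, abs=0.02)
        assert draws.std(ddof=1) == pytest.approx(0.6, abs=0.02)

    def test_identical_seed_identical_matrix(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(25, 2, (30, 3)), columns=list("abc"))
        values[values < 24] = np.nan
        m = LFQMatrix(values, {c: "g" for c in "abc"})
        out1 = impute_missing(m, ImputeConfig(seed=11))
        out2 = impute_missing(m, ImputeConfig(seed=11))
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_all_missing_column_rejected(self):
        values = pd.DataFrame({"a": [np.nan, np.nan], "b": [25.0, 26.0]})
        with pytest.raises(ValidationError):
            impute_missing(LFQMatrix(values, {"a": "g", "b": "g"}), ImputeConfig(seed=0))


def _complete_matrix(values, baits, reps):
    samples = [f"{b}_{r}" for b in baits for r in range(reps)]
    df = pd.DataFrame(values, columns=samples, index=[f"P{i}" for i in range(len(values))])
    return LFQMatrix(df, {s: s.rsplit("_", 1)[0] for s in samples})


class TestAnovaS0:
    def test_constant_protein_not_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(25, 1, (20, 8))
        values[0] = 25.0  # identical in all columns
        m = _complete_matrix(values, ("a", "b"), 4)
        res = anova_s0(m, AnovaConfig(s0=4.0, seed=0))
        assert res.d.iloc[0] == 0.0
        assert not res.significant.iloc[0]

    def test_s0_zero_ranking_matches_classic_f(self):
        # two groups, n=3 each: with s0 = 0 the moderated d is a monotone
        # transform of the one-way F statistic
        rng = np.random.default_rng(5)
        base = rng.normal(10, 1, (30, 6))
        base[:10, 3:] += rng.uniform(1, 3, (10, 3))  # some shifted proteins
        m = _complete_matrix(base, ("a", "b"), 3)
        res = anova_s0(m, AnovaConfig(s0=0.0, n_permutations=10, seed=0))
        f_stats = [
            stats.f_oneway(base[i, :3], base[i, 3:]).statistic for i in range(len(base))
        ]
        assert np.array_equal(np.argsort(res.d.to_numpy()), np.argsort(f_stats))

    def test_hand_computed_two_group_toy(self):
        # group means 10 and 12, within-group SD exactly computable
        values = np.array([[9.0, 10.0, 11.0, 11.0, 12.0, 13.0]])
        m = _complete_matrix(values, ("a", "b"), 3)
        res = anova_s0(m, AnovaConfig(s0=0.0, n_permutations=10, seed=0))
        # MS_between = 3*2*(1)^2/(2-1)... = 6; MS_within = 4/4 = 1 -> d = sqrt(6)
        assert res.d.iloc[0] == pytest.approx(np.sqrt(6.0), abs=1e-10)

    def test_q_values_monotone_in_d(self):
        rng = np.random.default_rng(6)
        values = rng.normal(25, 1, (60, 8))
        values[:5, 4:] += 5.0
        m = _complete_matrix(values, ("a", "b"), 4)
        res = anova_s0(m, AnovaConfig(s0=1.0, n_permutations=50, seed=1))
        order = np.argsort(-res.d.to_numpy())
        q_sorted = res.q.to_numpy()[order]
        assert (np.diff(q_sorted) >= -1e-12).all()

    def test_null_matrix_yields_no_hits_in_most_seeded_runs(self):
        clean = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            values = rng.normal(25, 1, (150, 12))
            m = _complete_matrix(values, ("a", "b", "c"), 4)
            res = anova_s0(m, AnovaConfig(s0=4.0, fdr_target=0.002, n_permutations=50, seed=seed))
            if res.significant.sum() == 0:
                clean += 1
        assert clean >= 95

    def test_determinism_with_seed(self):
        rng = np.random.default_rng(7)
        values = rng.normal(25, 1, (40, 8))
        m = _complete_matrix(values, ("a", "b"), 4)
        r1 = anova_s0(m, AnovaConfig(seed=3))
        r2 = anova_s0(m, AnovaConfig(seed=3))
        pd.testing.assert_series_equal(r1.q, r2.q)

    def test_incomplete_matrix_rejected(self):
        values = np.full((3, 4), 25.0)
        values[0, 0] = np.nan
        m = _complete_matrix(values, ("a", "b"), 2)
        with pytest.raises(ValidationError):
            anova_s0(m, AnovaConfig(seed=0))


class TestClustering:
    def _pipeline(self, seed=1):
        table, truth = simulate_lfq(LfqSimSpec(seed=seed))
        m = load_and_filter_lfq(table, truth["groups"])
        m = impute_missing(m, ImputeConfig(seed=seed))
        res = anova_s0(m, AnovaConfig(seed=seed))
        return m, res, truth

    def test_zscored_rows_have_mean_zero_sd_one(self):
        m, res, _ = self._pipeline()
        out = profile_and_cluster(m, res)
        assert np.allclose(out.zscores.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.zscores.std(axis=1, ddof=0), 1.0, atol=1e-10)

    def test_planted_clusters_recovered_with_high_ari(self):
        m, res, truth = self._pipeline()
        out = profile_and_cluster(m, res, n_clusters=3)
        planted = set(truth["planted"]) & set(out.cluster_ids.index)
        labels_true = [truth["cluster_of"][p] for p in sorted(planted)]
        labels_pred = [out.cluster_ids[p] for p in sorted(planted)]
        assert adjusted_rand_score(labels_true, labels_pred) >= 0.9

    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(8)
        values = rng.normal(25, 1, (10, 8))
        values[0, 4:] += 6
        values[1] = values[0]  # exact duplicate
        values[2, 4:] -= 6
        m = _complete_matrix(values, ("a", "b"), 4)
        res = anova_s0(m, AnovaConfig(s0=0.5, fdr_target=0.05, seed=0))
        assert res.significant.loc["P0"] and res.significant.loc["P1"]
        out = profile_and_cluster(m, res, n_clusters=2)
        assert out.linkage is not None
        first_merge = set(out.linkage[0, :2].astype(int))
        idx = {p: i for i, p in enumerate(out.zscores.index)}
        assert first_merge == {idx["P0"], idx["P1"]}

    def test_degenerate_single_significant_protein(self):
        rng = np.random.default_rng(9)
        values = rng.normal(25, 0.5, (10, 8))
        values[0, 4:] += 8
        m = _complete_matrix(values, ("a", "b"), 4)
        res = anova_s0(m, AnovaConfig(s0=0.5, fdr_target=0.002, seed=0))
        out = profile_and_cluster(m, res)
        assert out.degenerate

    def test_bait_correlation_duplicated_and_negated_columns(self):
        z = pd.DataFrame(
            np.random.default_rng(10).normal(0, 1, (6, 4)),
            columns=["a_1", "a_2", "b_1", "b_2"],
            index=[f"P{i}" for i in range(6)],
        )
        z["b_1"] = z["a_1"]
        z["b_2"] = z["a_2"]
        m = LFQMatrix(z, {"a_1": "a", "a_2": "a", "b_1": "b", "b_2": "b"})
        from ubkit.aems import ClusterOutput, _bait_medians

        medians = _bait_medians(z, m)
        out = ClusterOutput(z, medians, pd.Series(1, index=z.index), None, list(z.index))
        corr = bait_correlation(out)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        out.bait_medians["b"] = -out.bait_medians["a"]
        corr = bait_correlation(out)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)


class TestTargetedMsRatios:
    def test_prm_normalization(self):
        assert prm_normalize(100.0, 1000.0) == pytest.approx(0.1)
        assert prm_normalize(200.0, 2000.0) == pytest.approx(0.1)
        with pytest.raises(ValidationError):
            prm_normalize(100.0, 0.0)

    @pytest.mark.parametrize(
        "acetylated, deacetylated, expected",
        [(0.0, 50.0, 1.0), (50.0, 50.0, 0.5), (100.0, 0.0, 0.0)],
    )
    def test_deacetylation_fraction(self, acetylated, deacetylated, expected):
        assert deacetylation_fraction(acetylated, deacetylated) == pytest.approx(expected)

    def test_both_areas_zero_rejected(self):
        with pytest.raises(ValidationError):
            deacetylation_fraction(0.0, 0.0)
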