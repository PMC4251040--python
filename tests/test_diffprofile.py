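import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import massbin as mb
from massbin.diffprofile import FeatureTable, PreprocessingOrderError, \
    iqr_filter_fraction


def make_table(values, groups=None, provenance=()):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        samples=[f"s{i}" for i in range(n)],
        groups=list(groups) if groups is not None else ["G"] * n,
        feature_labels=[f"f{j}" for j in range(p)],
        values=values, provenance=provenance)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


class TestIqrFilter:
    @pytest.mark.parametrize("n,frac", [
        (100, 0.05), (250, 0.05), (251, 0.10), (500, 0.10),
        (501, 0.25), (700, 0.25), (1000, 0.25), (1001, 0.40),
    ])
    def test_fraction_schedule(self, n, frac):
        assert iqr_filter_fraction(n) == frac

    def test_700_features_keep_525(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.uniform(0, 10, size=(8, 700)))
        filtered = mb.iqr_filter(table)
        assert filtered.n_features == 525  # floor(0.25 * 700) removed

    def test_100_features_remove_5(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.uniform(0, 10, size=(6, 100)))
        assert mb.iqr_filter(table).n_features == 95

    def test_high_iqr_spiked_features_retained(self):
        """Features with 100x the IQR of the noise background all survive,
        matching a direct IQR ranking."""
        rng = np.random.default_rng(2)
        noise = rng.uniform(0, 1, size=(10, 690))
        spiked = rng.uniform(0, 100, size=(10, 10))
        values = np.hstack([noise, spiked])
        table = make_table(values)
        filtered = mb.iqr_filter(table)
        spiked_labels = {f"f{j}" for j in range(690, 700)}
        assert spiked_labels <= set(filtered.feature_labels)
        # oracle: the removed set is exactly the lowest-IQR floor(0.25N)
        iqr = np.percentile(values, 75, axis=0) - np.percentile(values, 25,
                                                                axis=0)
        expect_removed = {f"f{j}" for j in np.argsort(iqr, kind="stable")[:175]}
        assert set(table.feature_labels) - set(filtered.feature_labels) \
            == expect_removed

    def test_refiltering_is_an_error(self):
        table = make_table(np.random.default_rng(3).uniform(0, 1, (4, 20)))
        filtered = mb.iqr_filter(table)
        with pytest.raises(PreprocessingOrderError):
            mb.iqr_filter(filtered)


class TestSumNormalize:
    def test_rows_divided_by_row_sum(self):
        table = make_table([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]])
        normalized = mb.sum_normalize(table)
        np.testing.assert_allclose(normalized.values[0], [0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalized.values.sum(axis=1), 1.0)

    def test_simplex_rows_unchanged(self):
        table = make_table([[0.2, 0.3, 0.5]])
        np.testing.assert_allclose(mb.sum_normalize(table).values,
                                   [[0.2, 0.3, 0.5]])

    def test_zero_total_row_names_sample(self):
        table = make_table([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="s1"):
            mb.sum_normalize(table)

    def test_normalize_after_log2_rejected(self):
        table = make_table([[1.0, 2.0]], provenance=("normalized", "log2"))
        with pytest.raises(PreprocessingOrderError):
            mb.sum_normalize(table)


class TestLog2Transform:
    def test_pseudocount_is_half_min_positive(self):
        table = make_table([[1.0, 2.0, 4.0]], provenance=("normalized",))
        out = mb.log2_transform(table)
        np.testing.assert_allclose(out.values, [np.log2([1.5, 2.5, 4.5])])

    def test_zeros_survive_via_pseudocount(self):
        table = make_table([[0.0, 0.5, 1.0]], provenance=("normalized",))
        out = mb.log2_transform(table)
        np.testing.assert_allclose(
            out.values, [np.log2(np.array([0.0, 0.5, 1.0]) + 0.25)])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_row_ordering_preserved(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.exponential(1.0, size=(4, 12))
        values[rng.uniform(size=values.shape) < 0.2] = 0.0
        if values.sum(axis=1).min() == 0:
            values[:, 0] += 1.0
        table = mb.sum_normalize(make_table(values))
        out = mb.log2_transform(table)
        for before, after in zip(table.values, out.values):
            np.testing.assert_array_equal(np.argsort(before, kind="stable"),
                                          np.argsort(after, kind="stable"))

    def test_requires_normalized_table(self):
        with pytest.raises(PreprocessingOrderError):
            mb.log2_transform(make_table([[1.0, 2.0]]))


class TestAutoscale:
    def test_two_sample_column(self):
        table = make_table([[1.0, 5.0], [3.0, 5.0]],
                           provenance=("normalized", "log2"))
        out = mb.autoscale(table)
        np.testing.assert_allclose(out.values[:, 0],
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_columns_standardized(self):
        rng = np.random.default_rng(8)
        table = make_table(rng.normal(size=(9, 5)),
                           provenance=("normalized", "log2"))
        out = mb.autoscale(table)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0,
                                   atol=1e-9)

    def test_constant_column_zeroed_with_warning(self, caplog):
        table = make_table([[1.0, 5.0], [3.0, 5.0]],
                           provenance=("normalized", "log2"))
        with caplog.at_level(logging.WARNING, logger="massbin.diffprofile"):
            out = mb.autoscale(table)
        np.testing.assert_array_equal(out.values[:, 1], [0.0, 0.0])
        assert any("constant" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def brute_force_pca(values):
    """Oracle: eigendecomposition of the covariance matrix."""
    X = values - values.mean(axis=0)
    cov = X.T @ X
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.maximum(eigval, 0.0)
    scores = X @ eigvec
    frac = eigval / eigval.sum()
    return scores, frac


class TestPca:
    def test_two_samples_pc1_explains_everything(self):
        table = make_table([[1.0, 2.0, 3.0], [4.0, 0.0, 3.0]])
        result = mb.pca(table, n_components=1)
        assert result.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(12)
        table = make_table(rng.normal(size=(6, 4)),
                           provenance=("normalized", "log2"))
        scaled = mb.autoscale(table)
        result = mb.pca(scaled, n_components=4)
        np.testing.assert_allclose(result.scores @ result.loadings.T,
                                   scaled.values, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_eigendecomposition(self, seed):
        """Scores and explained variance agree with a brute-force
        eigendecomposition of the covariance matrix (up to sign)."""
        rng = np.random.default_rng(seed)
        n, p = rng.integers(3, 11), rng.integers(2, 11)
        values = rng.normal(size=(n, p))
        table = make_table(values)
        k = min(n - 1, p)
        result = mb.pca(table, n_components=k)
        oracle_scores, oracle_frac = brute_force_pca(values)
        np.testing.assert_allclose(result.explained_variance_fraction,
                                   oracle_frac[:k], atol=1e-8)
        np.testing.assert_allclose(np.abs(result.scores),
                                   np.abs(oracle_scores[:, :k]), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(13)
        table = make_table(rng.normal(size=(8, 6)))
        result = mb.pca(table, n_components=3)
        for j in range(3):
            i_star = np.argmax(np.abs(result.loadings[:, j]))
            assert result.loadings[i_star, j] > 0

    def test_component_scores_orthogonal(self):
        rng = np.random.default_rng(14)
        table = make_table(rng.normal(size=(10, 8)))
        result = mb.pca(table, n_components=4)
        gram = result.scores.T @ result.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_explained_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(15)
        table = make_table(rng.normal(size=(12, 9)))
        result = mb.pca(table, n_components=5)
        frac = result.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1 + 1e-9
        assert np.all(frac >= 0)

    def test_too_many_components_rejected(self):
        table = make_table(np.random.default_rng(16).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            mb.pca(table, n_components=4)

    def test_pc1_separates_groups_in_synthetic_study(self, full_study):
        """Orienting PC1 by the group-mean score difference, every sample's
        score sign matches its group."""
        runs, truth, grid, matrix = full_study
        result = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        sc = result.pca.scores[:, 0]
        ga = np.array(truth.groups) == truth.groups[0]
        if sc[ga].mean() < sc[~ga].mean():
            sc = -sc
        assert np.all(sc[ga] > 0) and np.all(sc[~ga] < 0)


class TestTopLoadings:
    def test_abs_ranking(self):
        result = mb.PcaResult(
            scores=np.zeros((2, 1)),
            loadings=np.array([[0.9], [-0.95], [0.1]]),
            explained_variance_fraction=np.array([1.0]),
            feature_labels=["f0", "f1", "f2"])
        top = mb.top_loadings(result, component=0, k=2)
        assert top["feature"].tolist() == ["f1", "f0"]

    def test_k_larger_than_feature_count(self):
        result = mb.PcaResult(
            scores=np.zeros((2, 1)), loadings=np.array([[0.5], [0.1]]),
            explained_variance_fraction=np.array([1.0]),
            feature_labels=["a", "b"])
        assert len(mb.top_loadings(result, k=30)) == 2

    def test_spiked_bins_dominate_pc1_loadings(self, full_study):
        """At least 80% of the spiked bins appear in the top 30 |loading|
        features of PC1, each with a direction label."""
        runs, truth, grid, matrix = full_study
        result = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        top = mb.top_loadings(result.pca, component=0, k=30,
                              normalized_table=result.normalized)
        labels = grid.labels()
        spiked = {labels[b] for b in truth.spiked_bins}
        hit = spiked & set(top["feature"])
        assert len(hit) >= 0.8 * len(spiked)
        assert set(top["direction"]) <= {"up_in_HL", "down_in_HL"}


# ---------------------------------------------------------------------------
# Welch t-test and volcano
# ---------------------------------------------------------------------------


def welch_oracle(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite df."""
    n1, n2 = len(a), len(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2 * sps.t.sf(abs(t), df)


class TestWelch:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 7), rng.integers(3, 7)
        a = rng.normal(0, 1, size=(n1, 1))
        b = rng.normal(0.5, 2, size=(n2, 1))
        p = mb.welch_ttest(a, b)[0]
        assert p == pytest.approx(welch_oracle(a[:, 0], b[:, 0]), abs=1e-10)

    def test_degenerate_constant_groups(self):
        a = np.full((3, 2), 5.0)
        b = np.hstack([np.full((3, 1), 5.0), np.full((3, 1), 7.0)])
        p = mb.welch_ttest(a, b)
        assert p[0] == 1.0 and p[1] == 0.0


def volcano_tables(norm_values, groups):
    norm = make_table(norm_values, groups=groups, provenance=("normalized",))
    trans = make_table(np.log2(np.asarray(norm_values) + 1e-6), groups=groups,
                       provenance=("normalized", "log2"))
    return norm, trans


class TestVolcano:
    def test_fold_change_ratio_of_group_means(self):
        rng = np.random.default_rng(20)
        a = 8.0 + rng.normal(0, 0.01, size=(5, 1))
        b = 2.0 + rng.normal(0, 0.01, size=(5, 1))
        norm, trans = volcano_tables(np.vstack([a, b]), ["A"] * 5 + ["B"] * 5)
        result = mb.volcano(norm, trans, fc_thresh=4.0, p_thresh=1e-10)
        assert result.fold_change[0] == pytest.approx(
            a.mean() / b.mean(), rel=1e-12)
        expected_flag = result.p_value[0] < 1e-10
        assert bool(result.significant_up[0]) == expected_flag

    def test_identical_groups_not_significant(self):
        values = np.tile([3.0, 5.0], (6, 1))
        norm, trans = volcano_tables(values, ["A"] * 3 + ["B"] * 3)
        result = mb.volcano(norm, trans)
        np.testing.assert_allclose(result.fold_change, 1.0)
        assert np.all(result.p_value == 1.0)
        assert not result.significant.any()

    def test_downregulation_flagged(self):
        a = np.full((4, 1), 1.0)
        b = np.full((4, 1), 10.0)
        norm, trans = volcano_tables(np.vstack([a, b]), ["A"] * 4 + ["B"] * 4)
        result = mb.volcano(norm, trans)
        # constant groups -> p = 0 (deterministic difference), FC = 0.1
        assert result.significant_down[0]

    def test_zero_denominator_reported_inf(self):
        a = np.full((3, 1), 2.0)
        b = np.zeros((3, 1))
        values = np.hstack([np.vstack([a, b]), np.ones((6, 1))])
        norm, trans = volcano_tables(values, ["A"] * 3 + ["B"] * 3)
        result = mb.volcano(norm, trans)
        assert np.isinf(result.fold_change[0])
        assert result.fc_undefined[0]

    def test_more_than_two_groups_rejected(self):
        norm, trans = volcano_tables(np.ones((6, 2)) + np.eye(6, 2),
                                     ["A", "A", "B", "B", "C", "C"])
        with pytest.raises(ValueError):
            mb.volcano(norm, trans)

    def test_spiked_bins_recovered_in_study(self, full_study):
        """All 10 bins spiked 8-fold are flagged at the default thresholds,
        with at most one false positive among the null bins."""
        runs, truth, grid, matrix = full_study
        result = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        labels = grid.labels()
        spiked = {labels[b] for b in truth.spiked_bins}
        v = result.volcano
        flagged = {v.feature_labels[i] for i in np.nonzero(v.significant)[0]}
        assert spiked <= flagged
        assert len(flagged - spiked) <= 1


# ---------------------------------------------------------------------------
# HCA
# ---------------------------------------------------------------------------


def lance_williams_ward(d):
    """Oracle: naive Ward (ward.D) agglomeration on the given dissimilarities."""
    n = d.shape[0]
    d = d.copy().astype(float)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    next_id = n
    members = {i: {i} for i in range(n)}
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        members[next_id] = members[i] | members[j]
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            nk, ni, nj = sizes[k], sizes[i], sizes[j]
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            dist[tuple(sorted((next_id, k)))] = dnew
        active = [k for k in active if k not in (i, j)] + [next_id]
        dist = {key: v for key, v in dist.items()
                if i not in key and j not in key}
        next_id += 1
    return np.array(heights), members


class TestHca:
    def test_perfectly_correlated_pair_merges_at_zero(self):
        table = make_table(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
        result = mb.hca(table, axis="samples")
        assert result.linkage.shape == (1, 4)
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pairs_recovered_at_k2(self):
        """Four samples forming two uncorrelated pairs: the k=2 cut recovers
        the pairing that direct enumeration of the 3 pairings selects."""
        rng = np.random.default_rng(30)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        values = np.vstack([a, a + rng.normal(0, 0.01, 12),
                            b, b + rng.normal(0, 0.01, 12)])
        table = make_table(values)
        labels = mb.hca(table, axis="samples").cut(2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        # enumeration oracle: the chosen pairing minimizes within-pair d
        from massbin.diffprofile import correlation_dissimilarity
        d = correlation_dissimilarity(values, ["a", "b", "c", "d"])
        pairings = {(0, 1, 2, 3): d[0, 1] + d[2, 3],
                    (0, 2, 1, 3): d[0, 2] + d[1, 3],
                    (0, 3, 1, 2): d[0, 3] + d[1, 2]}
        assert min(pairings, key=pairings.get) == (0, 1, 2, 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_match_lance_williams_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(6, 15))
        table = make_table(values)
        result = mb.hca(table, axis="samples")
        from massbin.diffprofile import correlation_dissimilarity
        d = correlation_dissimilarity(values,
                                      [f"s{i}" for i in range(6)])
        oracle_heights, _ = lance_williams_ward(d)
        np.testing.assert_allclose(result.linkage[:, 2], oracle_heights,
                                   rtol=1e-9, atol=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(31)
        table = make_table(rng.normal(size=(10, 20)))
        heights = mb.hca(table, axis="samples").linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_zero_variance_item_named_in_error(self):
        values = np.vstack([np.ones(5), np.arange(5.0)])
        table = make_table(values)
        with pytest.raises(ValueError, match="s0"):
            mb.hca(table, axis="samples")

    def test_feature_axis_clusters_features(self):
        rng = np.random.default_rng(32)
        table = make_table(rng.normal(size=(8, 5)))
        result = mb.hca(table, axis="features")
        assert result.items == table.feature_labels
        assert len(result.cut(2)) == 5

    def test_study_samples_cluster_by_group(self, full_study):
        runs, truth, grid, matrix = full_study
        result = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        cut = result.hca_samples.cut(2)
        ga = np.array(truth.groups) == truth.groups[0]
        assert len(set(cut[ga])) == 1 and len(set(cut[~ga])) == 1
        assert cut[ga][0] != cut[~ga][0]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class TestRunGroupAnalysis:
    def test_manifest_counts(self, small_study, tmp_path):
        runs, truth, grid, matrix = small_study
        result = mb.run_group_analysis(matrix, out_dir=str(tmp_path))
        csvs = [k for k in result.manifest if k.endswith(".csv")]
        pngs = [k for k in result.manifest if k.endswith(".png")]
        assert len(csvs) == 5 and len(pngs) == 3
        import os
        assert all(os.path.exists(p) for p in result.manifest.values())

    def test_single_group_skips_volcano(self, small_study, tmp_path):
        runs, truth, grid, matrix = small_study
        mono = mb.BinMatrix(grid=grid, samples=matrix.samples,
                            groups=["G"] * len(matrix.samples),
                            values=matrix.values)
        result = mb.run_group_analysis(mono, out_dir=str(tmp_path))
        assert result.volcano is None
        assert "volcano.csv" not in result.manifest
        assert "pca_scores.csv" in result.manifest
        assert "hca_linkage.csv" in result.manifest

    def test_pipeline_equals_manual_stages(self, small_study):
        runs, truth, grid, matrix = small_study
        auto = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        table = FeatureTable.from_bin_matrix(matrix)
        filtered = mb.iqr_filter(table)
        normalized = mb.sum_normalize(filtered)
        transformed = mb.log2_transform(normalized)
        scaled = mb.autoscale(transformed)
        np.testing.assert_array_equal(auto.scaled.values, scaled.values)
        manual_pca = mb.pca(scaled, n_components=2)
        np.testing.assert_allclose(auto.pca.scores, manual_pca.scores)
        manual_volcano = mb.volcano(normalized, scaled)
        np.testing.assert_allclose(auto.volcano.p_value,
                                   manual_volcano.p_value)
        np.testing.assert_allclose(auto.volcano.fold_change,
                                   manual_volcano.fold_change)
        manual_hca = mb.hca(scaled, axis="samples")
        np.testing.assert_allclose(auto.hca_samples.linkage,
                                   manual_hca.linkage)

    def test_preprocessing_poststates_hold(self, small_study):
        runs, truth, grid, matrix = small_study
        result = mb.run_group_analysis(matrix, out_dir=None, make_plots=False)
        np.testing.assert_allclose(result.normalized.values.sum(axis=1), 1.0)
        scaled = result.scaled.values
        nonconst = scaled.std(axis=0) > 0
        np.testing.assert_allclose(scaled[:, nonconst].mean(axis=0), 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(scaled[:, nonconst].std(axis=0, ddof=1),
                                   1.0, atol=1e-9)
        assert result.scaled.provenance == ("filtered", "normalized", "log2",
                                            "autoscaled")


class TestEffectMonotonicity:
    def test_loading_rank_improves_with_effect_size(self):
        """The spiked bins' median |PC1 loading| rank never worsens as the
        fold effect grows (2 -> 4 -> 8), everything else fixed."""
        ranks = []
        for fold in (2.0, 4.0, 8.0):
            runs, truth = mb.simulate_two_group_study(
                n_a=6, n_b=6, n_shared_peaks=30, n_spiked=10,
                effect_fold=fold, seed=42)
            grid = mb.make_grid(100.0, 1500.0, 2.0)
            matrix = mb.group_bin(runs, grid, truth.groups)
            result = mb.run_group_analysis(matrix, out_dir=None,
                                           make_plots=False)
            labels = [grid.labels()[b] for b in truth.spiked_bins]
            load = np.abs(result.pca.loadings[:, 0])
            order = np.argsort(-load, kind="stable")
            pos = {f: i for i, f in enumerate(result.pca.feature_labels)}
            rank_of = {int(f): r for r, f in enumerate(order)}
            ranks.append(np.median([rank_of[pos[l]] for l in labels
                                    if l in pos]))
        assert ranks[0] >= ranks[1] >= ranks[2]
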