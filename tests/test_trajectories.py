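"""Effect-size trajectories, k-means clusters, spline growth rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from dimorphmap import dimorphism, simulate, trajectories


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert trajectories.cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_hand_case(self):
        assert trajectories.cohens_d([2, 4], [1, 3]) == pytest.approx(0.7071067811865476)

    def test_matches_pooled_sd_formula(self):
        """ML variances make the scaling equal the classic pooled SD."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n0 = rng.integers(2, 12, size=2)
            m = rng.normal(size=n1)
            f = rng.normal(size=n0)
            s_pooled = np.sqrt(((n1 - 1) * np.var(m, ddof=1) + (n0 - 1) * np.var(f, ddof=1))
                               / (n1 + n0 - 2))
            expect = (m.mean() - f.mean()) / s_pooled
            assert trajectories.cohens_d(m, f) == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8),
           st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    def test_antisymmetry_under_group_swap(self, a, b):
        d1 = trajectories.cohens_d(a, b)
        d2 = trajectories.cohens_d(b, a)
        if np.isfinite(d1):
            assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_zero_variance_contract(self):
        assert trajectories.cohens_d([1.0, 1.0], [0.0, 0.0]) == np.inf
        assert np.isnan(trajectories.cohens_d([1.0, 1.0], [1.0, 1.0]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            trajectories.cohens_d([1.0], [1.0, 2.0])


class TestEffectSizeMatrix:
    def test_shape_is_voxels_by_timepoints(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mat = trajectories.effect_size_matrix(fields, truth)
        assert mat.values.shape == (truth.sum(), 9)
        assert np.isfinite(mat.values).all()

    def test_early_male_rows_positive_everywhere(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        roi1 = atlas.labels == 1
        mat = trajectories.effect_size_matrix(fields, roi1)
        assert (mat.values.mean(axis=0) > 0).all()

    def test_sign_convention_flips_with_sex_labels(self, relative_fields):
        fields, atlas, *_ = relative_fields
        roi = atlas.labels == 2
        mat = trajectories.effect_size_matrix(fields, roi)
        swapped = [simulate.DeterminantField(
            values=f.values, kind=f.kind, voxel_volume=f.voxel_volume,
            mouse_id=f.mouse_id, sex=("F" if f.sex == "M" else "M"),
            age_days=f.age_days) for f in fields]
        mat2 = trajectories.effect_size_matrix(swapped, roi)
        assert np.allclose(mat2.values, -mat.values, atol=1e-12)


class TestClustering:
    def test_k1_centroid_is_column_mean(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mat = trajectories.effect_size_matrix(fields, truth)
        res = trajectories.cluster_trajectories(mat, k=1, seed=0, k_diagnostic=range(1, 3))
        assert np.allclose(res.centroids[0], mat.values.mean(axis=0))

    def test_four_archetypes_recovered(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mat = trajectories.effect_size_matrix(fields, truth)
        res = trajectories.cluster_trajectories(mat, k=4, seed=0)
        true_labels = atlas.labels[truth]
        assert adjusted_rand_score(true_labels, res.labels) > 0.9
        assert set(res.wss_curve) == set(range(1, 9))

    def test_deterministic_given_seed(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mat = trajectories.effect_size_matrix(fields, truth)
        a = trajectories.cluster_trajectories(mat, k=4, seed=3, k_diagnostic=range(1, 2))
        b = trajectories.cluster_trajectories(mat, k=4, seed=3, k_diagnostic=range(1, 2))
        assert np.array_equal(a.labels, b.labels)

    def test_duplicated_rows_share_labels(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 9)) * 3
        mat = trajectories.EffectSizeMatrix(
            values=np.vstack([base, base]), ages=np.arange(9.0),
            voxel_coords=np.zeros((12, 3), dtype=int))
        res = trajectories.cluster_trajectories(mat, k=3, seed=0,
                                                k_diagnostic=range(1, 2))
        assert np.array_equal(res.labels[:6], res.labels[6:])

    def test_standardize_flag_clusters_by_shape(self):
        rng = np.random.default_rng(5)
        up = np.linspace(-1, 1, 9)
        down = -up
        rows = np.vstack([a * s + rng.normal(0, 0.01, 9)
                          for s in (up, down) for a in (1.0, 5.0)])
        mat = trajectories.EffectSizeMatrix(values=rows, ages=np.arange(9.0),
                                            voxel_coords=np.zeros((4, 3), int))
        res = trajectories.cluster_trajectories(mat, k=2, seed=0, standardize=True,
                                                k_diagnostic=range(1, 2))
        # same shape at different amplitudes lands in one cluster
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_fewer_rows_than_k_rejected(self):
        mat = trajectories.EffectSizeMatrix(values=np.zeros((2, 9)),
                                            ages=np.arange(9.0),
                                            voxel_coords=np.zeros((2, 3), int))
        with pytest.raises(ValueError):
            trajectories.cluster_trajectories(mat, k=4)


class TestGrowthSplines:
    def test_linear_series_selects_df1_with_exact_slope(self):
        ages = np.array([3, 5, 7, 10, 17, 23, 29, 36, 65], float)
        spline, df = trajectories.fit_growth_spline(ages, 0.3 * ages - 1.0)
        assert df == 1
        deriv = spline.derivative()(np.linspace(3, 65, 20))
        assert np.allclose(deriv, 0.3, atol=1e-8)

    def test_cubic_series_derivative_matches_analytic(self):
        ages = np.array([3, 5, 7, 10, 17, 23, 29, 36, 65], float)
        a, b, c, d = 1e-5, -2e-4, 0.01, 0.5
        y = a * ages**3 + b * ages**2 + c * ages + d
        spline, df = trajectories.fit_growth_spline(ages, y, candidate_df=[3])
        deriv = spline.derivative()(ages)
        assert np.allclose(deriv, 3 * a * ages**2 + 2 * b * ages + c, atol=1e-6)

    def test_aic_reaches_degree_on_noiseless_polynomials(self):
        ages = np.array([3, 5, 7, 10, 17, 23, 29, 36, 65], float)
        ok = 0
        rng = np.random.default_rng(1)
        trials = 40
        for _ in range(trials):
            g = rng.integers(1, 4)
            coefs = rng.normal(size=g + 1) * 10.0 ** (-np.arange(g + 1))[::-1]
            y = np.polyval(coefs, ages / 10.0)
            _, df = trajectories.fit_growth_spline(ages, y)
            ok += df >= g
        assert ok / trials >= 0.95

    def test_noise_tends_to_increase_selected_df(self):
        """A tendency check, not a hard per-trial assertion."""
        ages = np.array([3, 5, 7, 10, 17, 23, 29, 36, 65], float)
        rng = np.random.default_rng(2)
        clean_df, noisy_df = [], []
        for _ in range(100):
            y = 0.02 * ages
            _, d0 = trajectories.fit_growth_spline(ages, y)
            _, d1 = trajectories.fit_growth_spline(ages, y + rng.normal(0, 0.05, ages.size))
            clean_df.append(d0)
            noisy_df.append(d1)
        assert np.mean(noisy_df) >= np.mean(clean_df)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            trajectories.fit_growth_spline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestClusterSummaries:
    @pytest.fixture(scope="class")
    def clustered(self, relative_fields):
        fields, atlas, archs, truth = relative_fields
        mat = trajectories.effect_size_matrix(fields, truth)
        res = trajectories.cluster_trajectories(mat, k=4, seed=0,
                                                k_diagnostic=range(1, 2))
        return fields, atlas, mat, res

    def test_single_member_cluster_equals_its_row(self):
        mat = trajectories.EffectSizeMatrix(
            values=np.array([[1.0] * 9, [5.0] * 9]), ages=np.arange(9.0),
            voxel_coords=np.array([[0, 0, 0], [1, 1, 1]]))
        res = trajectories.ClusterResult(labels=np.array([1, 2]),
                                         centroids=mat.values.copy(),
                                         inertia=0.0, wss_curve={})
        summ = trajectories.cluster_summaries(res, mat)
        c1 = summ.volume_effect[summ.volume_effect.cluster == 1]
        assert np.allclose(c1["effect_size"], 1.0)

    def test_crossover_cluster_summary_crosses_zero(self, clustered):
        fields, atlas, mat, res = clustered
        # find the cluster dominated by the crossover archetype (label 3)
        true_labels = atlas.labels[tuple(mat.voxel_coords.T)]
        from scipy import stats as sps
        lab3 = sps.mode(res.labels[true_labels == 3], keepdims=False).mode
        summ = trajectories.cluster_summaries(res, mat)
        curve = summ.volume_effect[summ.volume_effect.cluster == lab3]
        at10 = curve.loc[curve.age_days == 10, "effect_size"].iloc[0]
        at36 = curve.loc[curve.age_days == 36, "effect_size"].iloc[0]
        assert at10 > 0 > at36

    def test_growth_rate_summary_female_biased_for_late_archetype(self, clustered):
        fields, atlas, mat, res = clustered
        true_labels = atlas.labels[tuple(mat.voxel_coords.T)]
        from scipy import stats as sps
        lab4 = sps.mode(res.labels[true_labels == 4], keepdims=False).mode
        mask4 = np.zeros(atlas.labels.shape, dtype=bool)
        mask4[tuple(mat.voxel_coords[res.labels == lab4].T)] = True
        growth = trajectories.growth_rate_curves(fields, mask4)
        sub_mat = trajectories.EffectSizeMatrix(
            values=mat.values[res.labels == lab4], ages=mat.ages,
            voxel_coords=mat.voxel_coords[res.labels == lab4])
        sub_res = trajectories.ClusterResult(
            labels=np.ones((res.labels == lab4).sum(), dtype=int),
            centroids=sub_mat.values.mean(axis=0, keepdims=True),
            inertia=0.0, wss_curve={})
        summ = trajectories.cluster_summaries(sub_res, sub_mat, growth)
        mid = summ.growth_effect[(summ.growth_effect.age_days >= 17)
                                 & (summ.growth_effect.age_days <= 29)]
        assert mid["effect_size"].min() < 0

    def test_empty_cluster_rejected(self):
        mat = trajectories.EffectSizeMatrix(values=np.zeros((3, 9)),
                                            ages=np.arange(9.0),
                                            voxel_coords=np.zeros((3, 3), int))
        res = trajectories.ClusterResult(labels=np.array([1, 1, 1]),
                                         centroids=np.zeros((2, 9)),
                                         inertia=0.0, wss_curve={})
        with pytest.raises(ValueError, match="empty"):
            trajectories.cluster_summaries(res, mat)
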