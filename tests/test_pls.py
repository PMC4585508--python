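"""Behavioral PLS: stack construction, SVD properties, resampling inference."""

import numpy as np
import pandas as pd
import pytest

from langmorph import BehavioralPLS, CohortMatrix
from langmorph.pls import build_correlation_stack, visualize_threshold

from conftest import small_spec, prepared_cohort


def line_matrix(data, tissue="GM"):
    data = np.asarray(data, dtype=float)
    V = data.shape[1]
    mask = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
    return CohortMatrix(data, mask, tissue, [f"s{i}" for i in range(len(data))],
                        (V, 1, 1), np.eye(4))


def simple_model(n=20, V=30, seed=0, measures=2, groups=None):
    rng = np.random.default_rng(seed)
    brain = {"GM": line_matrix(rng.normal(size=(n, V)))}
    beh = pd.DataFrame(rng.normal(size=(n, measures)),
                       columns=[f"m{i}" for i in range(measures)])
    return BehavioralPLS(brain, beh, groups=groups)


class TestCorrelationStack:
    def test_hand_computed_three_subject_case(self):
        # 3 subjects, 2 voxels, 1 measure: direct Pearson formula
        X = np.array([[1.0, 2.0], [2.0, 0.0], [3.0, 4.0]])
        y = np.array([[10.0], [20.0], [60.0]])
        stack = build_correlation_stack({"GM": X}, y, [np.arange(3)])
        for v in range(2):
            r = np.corrcoef(X[:, v], y[:, 0])[0, 1]
            assert stack[0, v] == pytest.approx(r, abs=1e-12)

    def test_null_cohort_entries_small(self):
        rng = np.random.default_rng(1)
        n, V = 200, 50
        stack = build_correlation_stack({"GM": rng.normal(size=(n, V))},
                                        rng.normal(size=(n, 2)), [np.arange(n)])
        # sampling error scale 1/sqrt(n): all |r| comfortably below 5/sqrt(n)
        assert np.abs(stack).max() < 5 / np.sqrt(n)

    def test_zero_variance_voxel_maps_to_zero(self):
        X = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        y = np.array([[1.0], [2.0], [3.0]])
        stack = build_correlation_stack({"GM": X}, y, [np.arange(3)])
        assert stack[0, 1] == 0.0

    def test_row_order_is_group_condition_measure(self):
        model = simple_model(n=12, measures=3, groups=np.array(["a"] * 6 + ["b"] * 6))
        assert model.block_rows == [("a", "GM", "m0"), ("a", "GM", "m1"), ("a", "GM", "m2"),
                                    ("b", "GM", "m0"), ("b", "GM", "m1"), ("b", "GM", "m2")]


class TestDecomposition:
    def test_rank_one_stack_fully_explained(self):
        X = np.outer(np.arange(1, 7.0), np.ones(4)) + np.arange(4)
        y = np.arange(1, 7.0)[:, None]  # behavior == voxel pattern driver
        model = BehavioralPLS({"GM": line_matrix(X)}, pd.DataFrame(y, columns=["m"]))
        res = model.fit()
        assert res.covariance_explained[0] == pytest.approx(1.0)

    def test_explained_fraction_from_singular_values(self):
        model = simple_model(seed=2)
        res = model.fit()
        s = res.singular_values
        assert np.all(np.diff(s) <= 1e-12)            # nonincreasing
        assert res.covariance_explained.sum() == pytest.approx(1.0)
        assert res.covariance_explained[0] == pytest.approx(s[0] ** 2 / (s ** 2).sum())

    def test_matches_eigendecomposition_oracle(self):
        """SVD saliences agree with a brute-force eigendecomposition of RᵀR."""
        model = simple_model(n=10, V=5, measures=3, seed=3)
        R = model._stack(model.behavior.to_numpy())
        res = model.fit()
        evals, evecs = np.linalg.eigh(R.T @ R)
        order = np.argsort(evals)[::-1]
        for i in range(3):
            v = evecs[:, order[i]]
            assert abs(abs(v @ res.brain_saliences[:, i])) == pytest.approx(1.0, abs=1e-8)
            assert res.singular_values[i] ** 2 == pytest.approx(evals[order[i]], abs=1e-8)

    def test_saliences_unit_norm(self):
        res = simple_model(seed=4).fit()
        norms = np.linalg.norm(res.brain_saliences, axis=0)
        assert np.allclose(norms, 1.0)

    def test_all_zero_stack_rejected(self):
        X = np.tile(np.arange(4.0)[:, None], (1, 3))
        beh = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
        model = BehavioralPLS({"GM": line_matrix(np.ones((4, 3)) * 7)}, beh)
        with pytest.raises(ValueError, match="zero"):
            model.fit()

    def test_missing_behavior_rejected(self):
        rng = np.random.default_rng(5)
        beh = pd.DataFrame({"m": [1.0, np.nan, 3.0, 4.0]})
        with pytest.raises(ValueError, match="missing"):
            BehavioralPLS({"GM": line_matrix(rng.normal(size=(4, 3)))}, beh)


class TestPermutation:
    def test_embedded_latent_effect_hits_floor(self, latent_cohort):
        spec, (table, mats) = latent_cohort
        model = BehavioralPLS(mats, table[["VIQ", "FAS", "NWR"]])
        res = model.fit()
        p = res.permutation_test(n_perm=100, seed=0)
        assert p[0] == 0.0  # observed λ1 exceeds every permuted λ1

    def test_null_p_is_large_on_average(self):
        # single null model: p for LV1 should not be extreme
        model = simple_model(n=30, V=40, seed=6)
        res = model.fit()
        p = res.permutation_test(n_perm=200, seed=1)
        assert p[0] > 0.01

    def test_determinism(self):
        model = simple_model(seed=7)
        res = model.fit()
        p1 = res.permutation_test(n_perm=100, seed=5)
        p2 = model.fit().permutation_test(n_perm=100, seed=5)
        assert np.array_equal(p1, p2)


class TestBootstrap:
    def test_bootstrap_ratio_definition(self):
        # BR must equal salience / SE with SE from the aligned resamples
        model = simple_model(n=25, V=10, seed=8)
        res = model.fit()
        br = res.bootstrap(n_boot=200, seed=2)
        assert br.shape == res.brain_saliences.shape
        assert np.isfinite(br).all()

    def test_embedded_pattern_attains_reliable_ratios(self, latent_cohort):
        spec, (table, mats) = latent_cohort
        model = BehavioralPLS(mats, table[["VIQ", "FAS", "NWR"]])
        res = model.fit()
        res.bootstrap(n_boot=150, seed=3)
        br3d = np.abs(res.bootstrap_ratio_map(0))
        center = np.asarray(spec.grid_shape) // 2
        r0 = int(br3d[tuple(center)] > 0)  # center voxel is in-mask
        near = br3d[center[0] - 1:center[0] + 2,
                    center[1] - 1:center[1] + 2,
                    center[2] - 1:center[2] + 2]
        corner = br3d[1:3, 1:3, 1:3]
        assert near.max() > 2.5
        assert near.mean() > corner.mean()

    def test_ci_table_shape(self):
        model = simple_model(n=25, V=10, measures=2, seed=9)
        res = model.fit()
        res.bootstrap(n_boot=120, seed=4)
        ci = res.behavior_corr_ci
        assert list(ci.columns) == ["group", "condition", "measure", "r", "ci_low", "ci_high"]
        assert (ci["ci_low"] <= ci["ci_high"]).all()


class TestInvariancesAndVariants:
    def test_singular_values_invariant_to_behavior_sign_flip(self):
        model = simple_model(seed=10)
        res = model.fit()
        flipped = BehavioralPLS(model.brain, -model.behavior)
        res2 = flipped.fit()
        assert np.allclose(res.singular_values, res2.singular_values)

    def test_two_group_variant_agrees_with_one_group_under_identical_groups(self):
        """With statistically identical halves, 1- and 2-group LV1 saliences align."""
        from langmorph.cohort import EffectBlob
        spec = small_spec(
            n_per_group={"ASC_delay": 20, "ASC_nodelay": 20}, grid_shape=(16, 16, 16),
            latent_loadings={"VIQ": 0.7, "FAS": 0.7, "NWR": 0.7, "ADIR-S": 0.0},
            latent_spatial_pattern=[
                EffectBlob((0.0, 0.0, 0.0), 8.0, 0.08, tissue="GM"),
                EffectBlob((-10.0, 10.0, -8.0), 8.0, -0.08, tissue="GM")],
            seed=13)
        table, mats = prepared_cohort(spec, tissues=("GM",))
        beh = table[["VIQ", "FAS", "NWR"]]
        one = BehavioralPLS(mats, beh).fit()
        two = BehavioralPLS(mats, beh, groups=table["delay_status"].to_numpy()).fit()
        r = np.corrcoef(one.brain_saliences[:, 0], two.brain_saliences[:, 0])[0, 1]
        assert abs(r) > 0.9

    def test_brain_scores_are_projections(self):
        model = simple_model(n=15, V=8, seed=11)
        res = model.fit()
        from langmorph.pls import _zscore_cols
        Z, _ = _zscore_cols(model.brain["GM"].data)
        assert np.allclose(res.brain_scores("GM"), Z @ res.brain_saliences)


class TestVisualizeThreshold:
    def test_all_subthreshold_empty(self):
        br = np.full((10, 10, 10), 1.0)
        assert not visualize_threshold(br, 2.5, 4).any()

    def test_cluster_size_rule(self):
        br = np.zeros((12, 12, 12))
        br[2:7, 2:7, 2:7] = 3.0        # 125 voxels: retained at min_cluster 100
        br[9:11, 9:11, 9:11] = 3.0     # 8 voxels: dropped
        out = visualize_threshold(br, 2.5, 100)
        assert out[3, 3, 3] == 3.0
        assert out[9, 9, 9] == 0.0

    def test_zero_cut_keeps_everything_above_cluster_size(self):
        br = np.ones((8, 8, 8))
        out = visualize_threshold(br, 0.0, 10)
        assert (out == 1.0).all()

    def test_negative_clusters_handled_separately(self):
        br = np.zeros((12, 12, 12))
        br[2:7, 2:7, 2:7] = -3.0
        out = visualize_threshold(br, 2.5, 100)
        assert out[3, 3, 3] == -3.0
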