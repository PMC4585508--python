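"""Sphere ROIs, extraction, group t-tests, and MANCOVA Hotelling trace."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from langmorph import (
    CohortMatrix,
    VolumeGrid,
    extract_roi_means,
    make_sphere_roi,
    mancova_hotelling,
    roi_group_test,
)
from langmorph.roi import NOMINAL_LANGUAGE_ROIS

from conftest import small_spec, prepared_cohort
from langmorph.cohort import EffectBlob


def unit_grid(shape=(21, 21, 21), voxel=1.0):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    return VolumeGrid(np.zeros(shape), aff)


class TestMakeSphereROI:
    def test_zero_radius_is_containing_voxel(self):
        g = unit_grid()
        roi = make_sphere_roi((0.0, 0.0, 0.0), 0.0, g)
        assert roi.voxel_index.shape == (1, 3)
        assert (roi.voxel_index[0] == [10, 10, 10]).all()

    def test_radius_one_gives_center_plus_face_neighbors(self):
        roi = make_sphere_roi((0.0, 0.0, 0.0), 1.0, unit_grid())
        assert roi.voxel_index.shape[0] == 7

    def test_radius_six_matches_brute_force_lattice_count(self):
        g = unit_grid((31, 31, 31))
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, g)
        # independent brute force: integer lattice points with |x|² ≤ 36
        count = sum(1 for x in range(-6, 7) for y in range(-6, 7) for z in range(-6, 7)
                    if x * x + y * y + z * z <= 36)
        assert roi.voxel_index.shape[0] == count

    def test_monotone_in_radius(self):
        g = unit_grid((31, 31, 31))
        sizes = [make_sphere_roi((0.0, 0.0, 0.0), r, g).voxel_index.shape[0]
                 for r in (0, 2, 4, 6, 8)]
        assert sizes == sorted(sizes)

    def test_out_of_grid_center_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_sphere_roi((100.0, 0.0, 0.0), 6.0, unit_grid())

    def test_anisotropic_voxels_use_mm_distance(self):
        aff = np.diag([1.0, 1.0, 4.0, 1.0])
        g = VolumeGrid(np.zeros((9, 9, 9)), aff)
        roi = make_sphere_roi(g.vox_to_mm([[4, 4, 4]])[0], 2.0, g)
        # along z, 4-mm voxels: only the central plane is within 2 mm
        assert set(roi.voxel_index[:, 2]) == {4}


class TestExtraction:
    def _cohort(self, n=6, shape=(9, 9, 9), seed=0):
        rng = np.random.default_rng(seed)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -(np.asarray(shape) - 1)
        mask = np.argwhere(np.ones(shape, bool))
        data = rng.uniform(size=(n, mask.shape[0]))
        m = CohortMatrix(data, mask, "GM", [f"s{i}" for i in range(n)], shape, aff)
        return m, VolumeGrid(np.zeros(shape), aff)

    def test_constant_map_gives_constant_mean(self):
        m, g = self._cohort()
        m.data[:] = 0.42
        roi = make_sphere_roi((0.0, 0.0, 0.0), 5.0, g)
        assert np.allclose(extract_roi_means(m, roi), 0.42)

    def test_single_voxel_roi_returns_that_voxel(self):
        m, g = self._cohort()
        roi = make_sphere_roi((0.0, 0.0, 0.0), 0.0, g)
        lut = {tuple(v): j for j, v in enumerate(m.mask_index)}
        j = lut[tuple(roi.voxel_index[0])]
        assert np.allclose(extract_roi_means(m, roi), m.data[:, j])

    def test_matches_hand_computed_mean(self):
        m, g = self._cohort(n=5, seed=3)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 4.0, g)
        lut = {tuple(v): j for j, v in enumerate(m.mask_index)}
        cols = [lut[tuple(v)] for v in roi.voxel_index]
        assert np.allclose(extract_roi_means(m, roi), m.data[:, cols].mean(axis=1))

    def test_commutes_with_subject_reordering(self):
        m, g = self._cohort(n=6, seed=4)
        roi = make_sphere_roi((0.0, 0.0, 0.0), 4.0, g)
        perm = np.array([3, 1, 5, 0, 2, 4])
        means = extract_roi_means(m, roi)
        means_perm = extract_roi_means(m.subset(perm), roi)
        assert np.allclose(means[perm], means_perm)

    def test_roi_outside_mask_rejected(self):
        m, g = self._cohort()
        m2 = CohortMatrix(m.data[:, :1], m.mask_index[:1], "GM", m.subjects,
                          m.grid_shape, m.affine)
        roi = make_sphere_roi((6.0, 6.0, 6.0), 1.0, g)
        with pytest.raises(ValueError, match="outside the cohort mask"):
            extract_roi_means(m2, roi)


class TestGroupTest:
    def test_identical_groups_give_zero(self):
        vals = np.r_[np.arange(5.0), np.arange(5.0)]
        labels = np.array(["a"] * 5 + ["b"] * 5)
        out = roi_group_test(vals, labels)
        assert out["t"] == 0.0 and out["d"] == 0.0

    def test_matches_textbook_two_sample_t(self):
        rng = np.random.default_rng(5)
        vals = np.r_[rng.normal(size=10), rng.normal(0.8, 1.0, size=12)]
        labels = np.array(["a"] * 10 + ["b"] * 12)
        out = roi_group_test(vals, labels)
        t_ref, p_ref = stats.ttest_ind(vals[:10], vals[10:], equal_var=True)
        assert out["t"] == pytest.approx(t_ref)
        assert out["p"] == pytest.approx(p_ref)
        assert out["df"] == 20

    def test_embedded_deficit_reproduces_direction(self):
        """A delay-group volume deficit yields negative t (delay < no-delay)."""
        spec = small_spec(
            n_per_group={"ASC_delay": 20, "ASC_nodelay": 20}, grid_shape=(16, 16, 16),
            effect_blobs=[EffectBlob((0.0, 0.0, 0.0), 6.0, -0.12, groups=("ASC_delay",)),
                          EffectBlob((10.0, -10.0, 8.0), 6.0, 0.12, groups=("ASC_delay",))],
            seed=17)
        table, mats = prepared_cohort(spec)
        grid = VolumeGrid(np.zeros(spec.grid_shape), spec.affine())
        roi = make_sphere_roi((0.0, 0.0, 0.0), 6.0, grid)
        vals = extract_roi_means(mats["GM"], roi)
        out = roi_group_test(vals, table["delay_status"].to_numpy())
        assert out["t"] < 0  # first label is 'delay'
        assert out["p"] < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            roi_group_test(np.ones(8), np.array(["a"] * 4 + ["b"] * 4))


class TestMancova:
    def test_identical_groups_give_zero_trace(self):
        A = np.random.default_rng(0).normal(size=(6, 3))
        Y = np.vstack([A, A])  # the two groups are literally the same data
        labels = np.array(["a"] * 6 + ["b"] * 6)
        out = mancova_hotelling(Y, labels)
        assert out["hotelling_trace"] < 1e-20

    def test_one_response_reduces_to_squared_t(self):
        rng = np.random.default_rng(6)
        y = np.r_[rng.normal(size=12), rng.normal(1.0, 1.0, size=10)][:, None]
        labels = np.array(["a"] * 12 + ["b"] * 10)
        out = mancova_hotelling(y, labels)
        t_ref, p_ref = stats.ttest_ind(y[:12, 0], y[12:, 0], equal_var=True)
        assert out["F"] == pytest.approx(t_ref ** 2)
        assert out["p"] == pytest.approx(p_ref)

    def test_matches_statsmodels_manova_oracle(self):
        """Hotelling–Lawley trace and F agree with statsmodels MANOVA."""
        rng = np.random.default_rng(7)
        n, p = 40, 4
        Y = rng.normal(size=(n, p))
        labels = np.array(["a"] * 20 + ["b"] * 20)
        age = rng.uniform(18, 40, n)
        out = mancova_hotelling(Y, labels, covariates=age[:, None])
        from statsmodels.multivariate.manova import MANOVA
        df = pd.DataFrame(Y, columns=[f"y{i}" for i in range(p)])
        df["group"] = (labels == "a").astype(float)
        df["age"] = age
        mv = MANOVA.from_formula(" + ".join(df.columns[:p]) + " ~ group + age", data=df)
        tab = mv.mv_test().results["group"]["stat"]
        assert out["hotelling_trace"] == pytest.approx(
            tab.loc["Hotelling-Lawley trace", "Value"], rel=1e-6)
        assert out["F"] == pytest.approx(tab.loc["Hotelling-Lawley trace", "F Value"], rel=1e-6)

    def test_df_convention_matches_published_shape(self):
        # 13 responses, n = 80, group + age + 2 center dummies -> F(13, 63)
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(80, 13))
        labels = np.array(["a"] * 38 + ["b"] * 42)
        cov = np.column_stack([rng.uniform(18, 40, 80),
                               np.r_[np.ones(40), np.zeros(40)],
                               np.r_[np.zeros(40), np.tile([1.0, 0.0], 20)]])
        out = mancova_hotelling(Y, labels, covariates=cov)
        assert (out["df1"], out["df2"]) == (13, 63)

    def test_too_many_responses_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="too few"):
            mancova_hotelling(rng.normal(size=(10, 8)), np.array(["a"] * 5 + ["b"] * 5))


def test_nominal_roi_list_has_13_entries():
    assert len(NOMINAL_LANGUAGE_ROIS) == 13
    labels = [r[0] for r in NOMINAL_LANGUAGE_ROIS]
    assert len(set(labels)) == 13
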