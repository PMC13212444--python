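"""Voxelwise GLM, SUVR scaling, smoothing, cluster inference, conjunction, ROI."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from lapet import petglm, synthetic
from lapet.volume import VolumeImage


def _vol(data, mask=None, voxel_mm=4.0):
    data = np.asarray(data, dtype=float)
    return VolumeImage(data, synthetic.default_affine(data.shape, voxel_mm),
                       mask=mask)


class TestProportionalScale:
    def test_constant_volume_becomes_ones(self):
        v = petglm.proportional_scale(_vol(np.full((3, 3, 3), 7.0)))
        np.testing.assert_allclose(v.data, 1.0)
        assert v.is_scaled

    def test_scale_invariance(self, toy_volume):
        a = petglm.proportional_scale(toy_volume)
        b = petglm.proportional_scale(
            toy_volume.with_data(toy_volume.data * 3.7))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_two_pass_rule_hand_computed(self):
        """(8, 8, 8, 0.5): whole mean 6.125, threshold 0.7656 keeps the
        three 8s, global = 8 -> output (1, 1, 1, 0.0625)."""
        v = _vol(np.array([8.0, 8.0, 8.0, 0.5]).reshape(4, 1, 1))
        out = petglm.proportional_scale(v)
        np.testing.assert_allclose(out.data.ravel(), [1, 1, 1, 0.0625])

    def test_nonpositive_global_rejected(self):
        with pytest.raises(ValueError):
            petglm.proportional_scale(_vol(np.full((2, 2, 2), -1.0)))


class TestSmoothing:
    def test_fwhm_to_sigma_constant(self):
        assert 8.0 * petglm.FWHM_TO_SIGMA == pytest.approx(3.3972, abs=1e-4)

    def test_zero_fwhm_is_identity(self, toy_volume):
        out = petglm.smooth_gaussian(toy_volume, 0.0)
        np.testing.assert_array_equal(out.data, toy_volume.data)

    def test_interior_impulse_conserves_mass(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = petglm.smooth_gaussian(_vol(data), 8.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self, toy_volume):
        with pytest.raises(ValueError):
            petglm.smooth_gaussian(toy_volume, -1.0)

    def test_anisotropic_voxels_use_per_axis_sigma(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        aff = np.diag([2.0, 4.0, 8.0, 1.0])
        out = petglm.smooth_gaussian(VolumeImage(data, aff), 8.0)
        # wider spread along the finer-sampled axis, in voxel units
        profile_x = out.data[:, 10, 10]
        profile_z = out.data[10, 10, :]
        assert (profile_x > 1e-6).sum() > (profile_z > 1e-6).sum()


class TestVoxelwiseGLM:
    def test_zero_contrast_gives_zero_t(self, rng):
        vols = [_vol(rng.normal(size=(4, 4, 4))) for _ in range(10)]
        spec = petglm.DesignSpec.build(
            {"x": rng.normal(size=10)}, contrast={})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        np.testing.assert_allclose(stat.data, 0.0, atol=1e-12)

    def test_two_group_design_equals_scalar_t(self, rng):
        """Single-voxel volumes: the GLM t equals the pooled two-sample t."""
        a, b = rng.normal(size=12), rng.normal(loc=1.0, size=8)
        vols = [_vol(np.full((1, 1, 1), v)) for v in np.r_[a, b]]
        group = np.r_[np.ones(12), np.zeros(8)]
        spec = petglm.DesignSpec.build({"group": group},
                                       contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        t_ref = st.ttest_ind(a, b).statistic
        assert stat.data[0, 0, 0] == pytest.approx(t_ref, abs=1e-10)
        assert stat.df == 18

    def test_matches_per_voxel_ols_loop(self, rng):
        """6x6x6, n=20 random design: vectorized fit equals a literal
        per-voxel least-squares loop."""
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        c = np.array([0.0, 1.0, -0.5])
        Y = rng.normal(size=(n, 6, 6, 6))
        vols = [_vol(Y[i]) for i in range(n)]
        spec = petglm.DesignSpec(
            pd.DataFrame(X, columns=["intercept", "a", "b"]), c)
        stat = petglm.fit_voxelwise_glm(vols, spec)
        xtx_inv = np.linalg.inv(X.T @ X)
        cc = c @ xtx_inv @ c
        for idx in [(0, 0, 0), (3, 4, 5), (5, 5, 5), (2, 1, 4)]:
            y = Y[(slice(None),) + idx]
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            t_ref = (c @ beta) / np.sqrt(resid @ resid / (n - 3) * cc)
            assert stat.data[idx] == pytest.approx(t_ref, abs=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        with pytest.raises(ValueError, match="rank deficient"):
            petglm.DesignSpec.build(
                {"a": np.ones(8), "b": np.ones(8)}, contrast={"a": 1.0})

    def test_out_of_mask_voxels_are_nan(self, rng):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        vols = [_vol(rng.normal(size=(3, 3, 3)), mask=mask)
                for _ in range(8)]
        spec = petglm.DesignSpec.build({"x": rng.normal(size=8)},
                                       contrast={"x": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        assert np.isfinite(stat.data[1, 1, 1])
        assert np.isnan(stat.data[0, 0, 0])


def _null_volumes(n, shape, seed, mask):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = np.zeros(shape)
        d[mask] = 100.0
        noise = rng.standard_normal(shape)
        d += 4.0 * noise
        out.append(_vol(d, mask=mask))
    return out


class TestClusterInference:
    def test_forming_p_one_spans_mask(self, rng):
        mask = synthetic.ellipsoid_mask((8, 8, 8))
        vols = _null_volumes(14, (8, 8, 8), 0, mask)
        group = np.r_[np.ones(7), np.zeros(7)]
        spec = petglm.DesignSpec.build({"group": group},
                                       contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        res = petglm.cluster_inference(stat, forming_p=1.0,
                                       n_permutations=100, seed=0)
        assert len(res.table) == 1
        assert res.table.iloc[0]["extent"] == mask.sum()

    def test_no_suprathreshold_returns_empty_table(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        vols = _null_volumes(10, (5, 5, 5), 1, mask)
        spec = petglm.DesignSpec.build(
            {"group": np.r_[np.ones(5), np.zeros(5)]},
            contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        res = petglm.cluster_inference(stat, forming_p=1e-12,
                                       n_permutations=100, seed=0)
        assert len(res.table) == 0
        assert res.n_significant == 0

    def test_planted_cluster_recovered_with_dice(self):
        """A strongly planted group effect yields one significant cluster
        overlapping the truth mask with Dice > 0.5."""
        shape = (16, 20, 16)
        eff = synthetic.GroundTruthEffects.default(
            shape, group_hypo_amp=-10.0, group_hyper_amp=0.001,
            la_slope=0.0, interaction_slope_male=0.0,
            interaction_regional_sd=0.0, age_slope=0.0)
        subjects, _ = synthetic.generate_cohort(n_aud=16, n_hc=16, seed=2)
        vols = synthetic.generate_metabolic_volumes(
            subjects, eff, global_factor_sd=0.0, seed=3)
        group = (subjects["group"] == "AUD").to_numpy(float)
        spec = petglm.DesignSpec.build({"group": group},
                                       contrast={"group": 1.0}, direction=-1)
        stat = petglm.fit_voxelwise_glm(
            [vols[s] for s in subjects["subject_id"]], spec)
        res = petglm.cluster_inference(stat, n_permutations=300, seed=4)
        assert res.n_significant >= 1
        sig = np.isin(res.label_map, res.significant_ids())
        inter = (sig & eff.group_hypo_mask).sum()
        dice = 2 * inter / (sig.sum() + eff.group_hypo_mask.sum())
        assert dice > 0.5

    def test_permutation_seed_reproducible(self, rng):
        mask = np.ones((6, 6, 6), dtype=bool)
        vols = _null_volumes(12, (6, 6, 6), 5, mask)
        spec = petglm.DesignSpec.build(
            {"group": np.r_[np.ones(6), np.zeros(6)]},
            contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        r1 = petglm.cluster_inference(stat, forming_p=0.05,
                                      n_permutations=200, seed=9)
        r2 = petglm.cluster_inference(stat, forming_p=0.05,
                                      n_permutations=200, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        np.testing.assert_array_equal(r1.null_max_extent, r2.null_max_extent)

    def test_uncorrected_p_stable_when_doubling_permutations(self):
        mask = synthetic.ellipsoid_mask((10, 12, 10))
        vols = _null_volumes(16, (10, 12, 10), 6, mask)
        spec = petglm.DesignSpec.build(
            {"group": np.r_[np.ones(8), np.zeros(8)]},
            contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        r1 = petglm.cluster_inference(stat, forming_p=0.05,
                                      n_permutations=400, seed=1)
        r2 = petglm.cluster_inference(stat, forming_p=0.05,
                                      n_permutations=800, seed=2)
        if len(r1.table) and len(r2.table):
            p1 = r1.table.iloc[0]["p_uncorrected"]
            p2 = r2.table.iloc[0]["p_uncorrected"]
            assert abs(p1 - p2) < 2.0 / np.sqrt(400)


class TestConjunction:
    def _stat_pair(self, rng, overlap=True):
        mask = np.ones((8, 8, 8), dtype=bool)
        base = rng.normal(size=(20, 8, 8, 8))
        if overlap:
            base[:10, 2:5, 2:5, 2:5] += 4.0
        vols = [_vol(base[i], mask=mask) for i in range(20)]
        group = np.r_[np.ones(10), np.zeros(10)]
        spec = petglm.DesignSpec.build({"group": group},
                                       contrast={"group": 1.0})
        return petglm.fit_voxelwise_glm(vols, spec)

    def test_self_conjunction_is_idempotent(self, rng):
        m = self._stat_pair(rng)
        joint, _ = petglm.conjunction(m, m, forming_p=0.01)
        np.testing.assert_array_equal(joint, m.suprathreshold(0.01))

    def test_conjunction_is_exact_intersection(self, rng):
        a = self._stat_pair(rng)
        b = self._stat_pair(rng)
        joint, _ = petglm.conjunction(a, b, forming_p=0.05)
        np.testing.assert_array_equal(
            joint, a.suprathreshold(0.05) & b.suprathreshold(0.05))

    def test_disjoint_maps_give_empty_result(self, rng):
        a = self._stat_pair(rng, overlap=True)
        b = self._stat_pair(rng, overlap=False)
        joint, table = petglm.conjunction(a, b, forming_p=1e-6)
        assert not joint.any()
        assert len(table) == 0

    def test_mismatched_grids_rejected(self, rng):
        a = self._stat_pair(rng)
        mask = np.ones((5, 5, 5), dtype=bool)
        vols = _null_volumes(10, (5, 5, 5), 2, mask)
        spec = petglm.DesignSpec.build(
            {"group": np.r_[np.ones(5), np.zeros(5)]},
            contrast={"group": 1.0})
        b = petglm.fit_voxelwise_glm(vols, spec)
        with pytest.raises(ValueError):
            petglm.conjunction(a, b)


class TestPeaksAndROI:
    def test_world_coordinates_from_affine(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = [-40.0, -56.0, -30.0]
        v = VolumeImage(np.zeros((30, 40, 30)), aff)
        np.testing.assert_allclose(v.voxel_to_world([20, 30, 20])[0],
                                   [0.0, 4.0, 10.0])

    def test_single_voxel_cluster_single_peak(self, rng):
        mask = np.ones((6, 6, 6), dtype=bool)
        base = rng.normal(size=(16, 6, 6, 6)) * 0.1
        base[:8, 3, 3, 3] += 10.0
        vols = [_vol(base[i], mask=mask) for i in range(16)]
        spec = petglm.DesignSpec.build(
            {"group": np.r_[np.ones(8), np.zeros(8)]},
            contrast={"group": 1.0})
        stat = petglm.fit_voxelwise_glm(vols, spec)
        res = petglm.cluster_inference(stat, n_permutations=100, seed=0)
        assert len(res.table) >= 1
        peaks = petglm.peak_table(res)
        best = res.table.loc[res.table["peak_t"].idxmax(), "cluster_id"]
        top = peaks[peaks["cluster_id"] == best]
        assert tuple(top.iloc[0][["i", "j", "k"]]) == (3, 3, 3)
        # identity-scale affine centered: world coords follow the affine
        np.testing.assert_allclose(
            top.iloc[0][["x", "y", "z"]].to_numpy(dtype=float),
            stat.affine[:3, :3] @ np.array([3, 3, 3]) + stat.affine[:3, 3])

    def test_roi_mean_is_arithmetic_mean(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 2, 2] = True
        data = np.zeros((3, 3, 3))
        data[0, 0, 0], data[1, 1, 1], data[2, 2, 2] = 1.0, 2.0, 6.0
        means = petglm.extract_roi_means([_vol(data)], mask)
        assert means.iloc[0] == pytest.approx(3.0)

    def test_constant_volume_roi_mean(self, toy_volume):
        mask = np.ones(toy_volume.shape, dtype=bool)
        v = toy_volume.with_data(np.full(toy_volume.shape, 5.5))
        assert petglm.extract_roi_means([v], mask).iloc[0] == 5.5

    def test_empty_mask_rejected(self, toy_volume):
        with pytest.raises(ValueError, match="empty"):
            petglm.extract_roi_means([toy_volume],
                                     np.zeros(toy_volume.shape, bool))
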