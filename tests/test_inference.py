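"""Group GLM, smoothness estimation, Monte-Carlo cluster null, correction."""

import numpy as np
import pytest
from scipy import ndimage, stats

from wdhub import (DataQualityError, ModelError, SmoothnessEstimate, StatMap,
                   apply_cluster_correction, cluster_null, covariate_design,
                   estimate_smoothness, glm_map, group_design)
from wdhub.inference import standardize_maps, connectivity_structure

from conftest import make_geometry


def flood_fill_components(volume):
    """Brute-force 26-connectivity components via BFS (oracle)."""
    comps = []
    seen = np.zeros(volume.shape, dtype=bool)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(volume)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[d] < volume.shape[d] for d in range(3)) \
                        and volume[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestGLM:
    def test_two_group_contrast_equals_pooled_t(self, rng):
        geom = make_geometry((4, 4, 4))
        for _ in range(5):
            n1, n2 = rng.integers(4, 12, size=2)
            Y = rng.standard_normal((n1 + n2, geom.n_voxels))
            groups = np.array(["A"] * n1 + ["B"] * n2)
            X, c = group_design(groups, positive="A")
            stat, _ = glm_map(Y, X, c, geom)
            t_ref, _ = stats.ttest_ind(Y[:n1], Y[n1:], axis=0)
            assert np.allclose(stat.t_values, t_ref, atol=1e-10)
            assert stat.df == n1 + n2 - 2

    def test_covariate_contrast_equals_regression_slope_t(self, rng):
        geom = make_geometry((3, 3, 3))
        cov = rng.standard_normal(15)
        Y = rng.standard_normal((15, geom.n_voxels))
        X, c = covariate_design(cov)
        stat, _ = glm_map(Y, X, c, geom)
        for v in range(0, geom.n_voxels, 7):
            res = stats.linregress(cov, Y[:, v])
            t_ref = res.slope / res.stderr
            assert stat.t_values[v] == pytest.approx(t_ref, abs=1e-10)

    def test_identical_maps_give_zero_t(self, rng):
        geom = make_geometry((3, 3, 3))
        Y = np.tile(rng.standard_normal(geom.n_voxels), (8, 1))
        X, c = group_design(np.array(["A"] * 4 + ["B"] * 4), "A")
        stat, _ = glm_map(Y, X, c, geom)
        assert np.all(stat.t_values == 0)

    def test_rank_deficient_design_rejected(self, rng):
        geom = make_geometry((3, 3, 3))
        X = np.ones((8, 2))
        with pytest.raises(ModelError):
            glm_map(rng.standard_normal((8, geom.n_voxels)), X,
                    np.array([0.0, 1.0]), geom)

    def test_residuals_orthogonal_to_design(self, rng):
        geom = make_geometry((3, 3, 3))
        Y = rng.standard_normal((12, geom.n_voxels))
        X, c = group_design(np.array(["A"] * 6 + ["B"] * 6), "A")
        _, resid = glm_map(Y, X, c, geom)
        assert np.max(np.abs(X.T @ resid)) < 1e-9

    def test_standardize_maps(self, rng):
        M = rng.standard_normal((5, 100)) * 7 + 3
        Z = standardize_maps(M)
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=1), 1, atol=1e-12)


class TestSmoothness:
    def test_recovers_known_kernel(self, rng):
        shape, vox = (18, 18, 18), 2.0
        geom = make_geometry(shape, voxel_mm=vox)
        fwhm = 6.0
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        maps = []
        for _ in range(20):
            noise = rng.standard_normal(shape)
            maps.append(ndimage.gaussian_filter(noise, sigma_vox).ravel())
        est = estimate_smoothness(np.vstack(maps), geom)
        assert np.all(np.abs(est.fwhm_mm - fwhm) < 0.15 * fwhm)

    def test_unsmoothed_noise_gives_voxel_scale_fwhm(self, rng):
        geom = make_geometry((16, 16, 16), voxel_mm=2.0)
        maps = rng.standard_normal((20, geom.n_voxels))
        est = estimate_smoothness(maps, geom)
        assert np.all(est.fwhm_mm < 1.5 * 2.0)

    def test_voxel_size_carries_units(self, rng):
        shape = (14, 14, 14)
        maps = [ndimage.gaussian_filter(rng.standard_normal(shape), 1.5).ravel()
                for _ in range(10)]
        maps = np.vstack(maps)
        est1 = estimate_smoothness(maps, make_geometry(shape, voxel_mm=2.0))
        est2 = estimate_smoothness(maps, make_geometry(shape, voxel_mm=4.0))
        assert np.allclose(est2.fwhm_mm, 2.0 * est1.fwhm_mm, rtol=1e-10)

    def test_constant_residuals_rejected(self):
        geom = make_geometry((6, 6, 6))
        with pytest.raises(DataQualityError):
            estimate_smoothness(np.ones((4, geom.n_voxels)), geom)


class TestClusterNull:
    def test_deterministic_under_seed(self):
        geom = make_geometry((10, 10, 10), voxel_mm=2.0)
        sm = SmoothnessEstimate(fwhm_mm=np.array([6.0, 6.0, 6.0]))
        n1 = cluster_null(sm, geom, voxel_p=0.05, n_iter=200, seed=3)
        n2 = cluster_null(sm, geom, voxel_p=0.05, n_iter=200, seed=3)
        assert np.array_equal(n1.max_sizes, n2.max_sizes)
        assert n1.threshold_size == n2.threshold_size

    def test_liberal_voxel_p_fills_mask(self):
        geom = make_geometry((8, 8, 8), voxel_mm=2.0)
        sm = SmoothnessEstimate(fwhm_mm=np.array([4.0, 4.0, 4.0]))
        null = cluster_null(sm, geom, voxel_p=0.9999, n_iter=100, seed=0)
        # nearly the whole mask is one suprathreshold cluster each iteration
        assert np.median(null.max_sizes) > 0.95 * geom.n_voxels

    def test_threshold_controls_null_exceedance(self):
        geom = make_geometry((12, 12, 12), voxel_mm=2.0)
        sm = SmoothnessEstimate(fwhm_mm=np.array([5.0, 5.0, 5.0]))
        null = cluster_null(sm, geom, voxel_p=0.05, n_iter=400, seed=1)
        frac = np.mean(null.max_sizes >= null.threshold_size)
        assert frac <= 0.05


class TestClusterCorrection:
    def _stat(self, tvol, geom, df=18):
        return StatMap(t_values=tvol.ravel()[geom.indices], df=df,
                       contrast="test", geometry=geom)

    def test_no_suprathreshold_empty_table(self, rng):
        geom = make_geometry((6, 6, 6))
        stat = self._stat(0.1 * rng.standard_normal(geom.shape), geom)
        table = apply_cluster_correction(stat, threshold_size=2, voxel_p=0.05)
        assert len(table) == 0

    def test_planted_block_survival_boundary(self):
        geom = make_geometry((8, 8, 8))
        tvol = np.zeros(geom.shape)
        tvol[2:4, 2:4, 2] = 10.0          # block of 4 voxels
        stat = self._stat(tvol, geom)
        assert len(apply_cluster_correction(stat, 4, 0.05)) == 1
        assert len(apply_cluster_correction(stat, 5, 0.05)) == 0

    def test_cluster_sign_and_peak(self):
        geom = make_geometry((8, 8, 8))
        tvol = np.zeros(geom.shape)
        tvol[1:3, 1:3, 1:3] = -7.0
        tvol[2, 2, 2] = -9.5
        stat = self._stat(tvol, geom)
        table = apply_cluster_correction(stat, 2, 0.05)
        assert len(table) == 1
        cl = table.clusters[0]
        assert cl.sign == -1
        assert cl.peak_t == pytest.approx(-9.5)
        assert cl.peak_ijk == (2, 2, 2)

    def test_labeling_matches_flood_fill_oracle(self, rng):
        geom = make_geometry((10, 10, 10))
        for _ in range(10):
            supra = rng.random(geom.shape) < 0.25
            tvol = np.where(supra, 10.0, 0.0)
            table = apply_cluster_correction(self._stat(tvol, geom), 1, 0.05)
            got = {frozenset(
                tuple(np.unravel_index(geom.indices[v], geom.shape))
                for v in cl.voxel_indices) for cl in table}
            assert got == flood_fill_components(supra)

    def test_connectivity_structures(self):
        assert connectivity_structure(6).sum() == 7
        assert connectivity_structure(18).sum() == 19
        assert connectivity_structure(26).sum() == 27
        with pytest.raises(Exception):
            connectivity_structure(4)
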