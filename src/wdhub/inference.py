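"""Group-level GLMs on weighted-degree maps with Monte-Carlo cluster correction.

The inference chain: per-voxel ordinary least squares across subjects
(a two-group contrast or a within-group covariate slope); residual maps feed
a spatial-smoothness estimator; Gaussian random fields smoothed to the
estimated FWHM build a null distribution of maximal suprathreshold cluster
sizes; the observed t-map is thresholded voxelwise (two-tailed), connected
components are labeled, and clusters smaller than the null-derived extent
threshold are removed.

The null-map generator smooths white noise with an isotropic-per-axis
Gaussian kernel matched to the estimated FWHM — the classic cluster-simulation
approach — rather than a mixed/long-tailed autocorrelation model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .io import (ConfigurationError, DataQualityError, MaskGeometry,
                 ModelError, SchemaError)

logger = logging.getLogger("wdhub")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_RHO_FLOOR = 1e-8


@dataclass
class StatMap:
    """Per-voxel t-values for one contrast."""

    t_values: np.ndarray
    df: int
    contrast: str
    geometry: MaskGeometry

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if not np.all(np.isfinite(self.t_values)):
            raise SchemaError("t-map contains non-finite values")
        if self.df < 1:
            raise ModelError("df must be >= 1")


@dataclass
class Cluster:
    voxel_indices: np.ndarray    # positions in the mask-voxel ordering
    size: int
    peak_t: float                # signed t at the peak |t| voxel
    peak_ijk: tuple[int, int, int]

    @property
    def sign(self) -> int:
        return 1 if self.peak_t >= 0 else -1


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    cluster_threshold_size: int
    voxel_p_threshold: float

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def surviving_voxels(self, sign: int | None = None) -> np.ndarray:
        picked = [c.voxel_indices for c in self.clusters
                  if sign is None or c.sign == sign]
        if not picked:
            return np.array([], dtype=np.int64)
        return np.sort(np.concatenate(picked))

    def to_records(self) -> list[dict]:
        return [{"cluster": k + 1, "size_voxels": c.size,
                 "peak_t": c.peak_t, "peak_i": c.peak_ijk[0],
                 "peak_j": c.peak_ijk[1], "peak_k": c.peak_ijk[2],
                 "sign": c.sign}
                for k, c in enumerate(self.clusters)]


@dataclass
class SmoothnessEstimate:
    """Per-axis equivalent Gaussian-kernel FWHM of the residual maps, in mm."""

    fwhm_mm: np.ndarray

    def __post_init__(self) -> None:
        self.fwhm_mm = np.asarray(self.fwhm_mm, dtype=float)
        if self.fwhm_mm.shape != (3,) or np.any(self.fwhm_mm <= 0):
            raise SchemaError("fwhm_mm must be 3 positive per-axis values")


# ---------------------------------------------------------------------------
# Voxelwise GLM
# ---------------------------------------------------------------------------

def standardize_maps(maps: np.ndarray) -> np.ndarray:
    """Z-score each subject's map across in-mask voxels.

    Voxel-level degree maps carry a per-subject global mode: the joint FDR
    cutoff and overall retained-link density vary from subject to subject and
    shift every voxel's degree together. As is standard for voxel-wise
    centrality analyses, each map is standardized (zero mean, unit variance
    across voxels) before group modeling so contrasts test the spatial
    pattern of hubness rather than the global link density.
    """
    M = np.asarray(maps, dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DataQualityError("cannot standardize a constant map")
    return (M - mu) / sd

def glm_map(wd_maps: np.ndarray, design: np.ndarray, contrast: np.ndarray,
            geometry: MaskGeometry, contrast_name: str = "contrast"
            ) -> tuple[StatMap, np.ndarray]:
    """Per-voxel OLS t-map for one contrast, plus residual maps.

    ``wd_maps`` is subjects x voxels, ``design`` subjects x predictors
    (include the intercept column explicitly), ``contrast`` a predictor-length
    vector. With design [1, group_indicator] and contrast [0, 1] this is
    exactly the pooled-variance two-sample t-test at every voxel.

    Voxels with zero residual variance get t = 0 (with a logged warning).
    """
    Y = np.asarray(wd_maps, dtype=float)
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if Y.ndim != 2 or X.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise SchemaError("wd_maps and design must share the subject axis")
    n, p = X.shape
    if c.shape != (p,):
        raise SchemaError(f"contrast must have length {p}")
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("design matrix is rank deficient")
    if n < p + 2:
        raise ModelError(f"need at least {p + 2} subjects for {p} predictors")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                      # p x voxels
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    var_c = float(c @ xtx_inv @ c)
    se = np.sqrt(sigma2 * var_c)
    effect = c @ beta
    # voxels with (numerically) no residual variance: t defined as 0
    scale = np.sqrt((Y ** 2).mean(axis=0))
    zero = se <= 1e-10 * np.sqrt(var_c) * np.maximum(scale, 1e-300)
    if zero.any():
        logger.warning("t set to 0 at %d voxels with zero residual variance",
                       int(zero.sum()))
    t = np.where(zero, 0.0, effect / np.where(zero, 1.0, se))
    stat = StatMap(t_values=t, df=df, contrast=contrast_name,
                   geometry=geometry)
    return stat, resid


def group_design(groups: np.ndarray | list[str], positive: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """[intercept, indicator] design and contrast for ``positive`` minus rest."""
    groups = np.asarray(groups)
    indicator = (groups == positive).astype(float)
    if indicator.sum() == 0 or indicator.sum() == len(groups):
        raise ModelError("both groups must be non-empty")
    X = np.column_stack([np.ones(len(groups)), indicator])
    return X, np.array([0.0, 1.0])


def covariate_design(covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """[intercept, covariate] design and slope contrast."""
    covariate = np.asarray(covariate, dtype=float)
    X = np.column_stack([np.ones(covariate.size), covariate])
    return X, np.array([0.0, 1.0])


# ---------------------------------------------------------------------------
# Spatial smoothness from residual maps
# ---------------------------------------------------------------------------

def estimate_smoothness(residual_maps: np.ndarray,
                        geometry: MaskGeometry) -> SmoothnessEstimate:
    """Equivalent Gaussian-kernel FWHM per axis from residual maps.

    Uses the variance-of-spatial-derivatives estimator: for a field produced
    by smoothing white noise with a Gaussian kernel of width sigma, the
    lag-one autocorrelation along an axis is rho = exp(-d^2 / (4 sigma^2))
    with d the voxel size, and rho is estimated from in-mask neighbor pairs
    as 1 - var(diff) / (2 var). Pair variances are pooled across maps.
    """
    R = np.asarray(residual_maps, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise SchemaError("need >= 2 residual maps (maps x voxels)")
    if R.shape[1] != geometry.n_voxels:
        raise SchemaError("residual maps do not match the mask")
    var_m = R.var(axis=1, ddof=0).mean()
    if var_m <= 0:
        raise DataQualityError("residual maps are constant; "
                               "smoothness is undefined")
    fwhm = np.empty(3)
    vox = geometry.voxel_sizes_mm
    flat_idx = np.full(np.prod(geometry.shape), -1, dtype=np.int64)
    flat_idx[geometry.indices] = np.arange(geometry.n_voxels)
    idx_vol = flat_idx.reshape(geometry.shape)
    for ax in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[ax] = slice(0, -1)
        b[ax] = slice(1, None)
        ia, ib = idx_vol[tuple(a)], idx_vol[tuple(b)]
        pair = (ia >= 0) & (ib >= 0)
        if pair.sum() < 2:
            raise DataQualityError(f"too few in-mask neighbor pairs on axis {ax}")
        diffs = R[:, ib[pair]] - R[:, ia[pair]]
        var_d = (diffs ** 2).mean()
        rho = np.clip(1.0 - var_d / (2.0 * var_m), _RHO_FLOOR, 1.0 - _RHO_FLOOR)
        sigma_mm = np.sqrt(-vox[ax] ** 2 / (4.0 * np.log(rho)))
        fwhm[ax] = sigma_mm / FWHM_TO_SIGMA
    return SmoothnessEstimate(fwhm_mm=fwhm)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent null
# ---------------------------------------------------------------------------

def connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _max_cluster_size(supra_volume: np.ndarray, structure: np.ndarray) -> int:
    labeled, n = ndimage.label(supra_volume, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


@dataclass
class ClusterNull:
    max_sizes: np.ndarray
    threshold_size: int
    voxel_p: float
    alpha: float
    fwhm_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))


def cluster_null(smoothness: SmoothnessEstimate, geometry: MaskGeometry,
                 voxel_p: float = 0.05, n_iter: int = 10000,
                 seed: int | np.random.Generator = 0,
                 connectivity: int = 26, alpha: float = 0.05) -> ClusterNull:
    """Null distribution of the maximal suprathreshold cluster size.

    Each iteration draws Gaussian white noise on the grid, smooths it to the
    estimated per-axis FWHM, standardizes in-mask, thresholds two-tailed at
    ``voxel_p`` pooling the tails by absolute value, and records the largest
    suprathreshold cluster. The extent threshold is the smallest integer k
    such that the fraction of null maxima >= k is at most ``alpha``: keeping
    only clusters of at least k voxels controls the family-wise false-positive
    rate at alpha.
    """
    if n_iter < 100:
        raise ConfigurationError("n_iter must be >= 100")
    if not 0 < voxel_p <= 1:
        raise ConfigurationError("voxel_p must lie in (0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mask = geometry.mask_volume()
    if mask.sum() < 8:
        raise ConfigurationError("mask too small for cluster simulation")
    sigma_vox = smoothness.fwhm_mm * FWHM_TO_SIGMA / geometry.voxel_sizes_mm
    structure = connectivity_structure(connectivity)
    z_crit = stats.norm.ppf(1.0 - voxel_p / 2.0)

    max_sizes = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        noise = rng.standard_normal(geometry.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        vals = smooth.ravel()[geometry.indices]
        z = (vals - vals.mean()) / vals.std()
        supra = np.zeros(geometry.shape, dtype=bool)
        supra.ravel()[geometry.indices] = np.abs(z) > z_crit
        max_sizes[it] = _max_cluster_size(supra, structure)

    sizes = np.sort(max_sizes)
    allowed = int(np.floor(alpha * n_iter))
    threshold = int(sizes[n_iter - allowed - 1]) + 1 if allowed < n_iter else 1
    logger.info("cluster null: %d iterations, extent threshold %d voxels",
                n_iter, threshold)
    return ClusterNull(max_sizes=max_sizes, threshold_size=threshold,
                       voxel_p=voxel_p, alpha=alpha,
                       fwhm_mm=smoothness.fwhm_mm.copy())


# ---------------------------------------------------------------------------
# Cluster-extent correction of an observed t-map
# ---------------------------------------------------------------------------

def apply_cluster_correction(stat: StatMap, threshold_size: int,
                             voxel_p: float = 0.05,
                             connectivity: int = 26) -> ClusterTable:
    """Two-tailed voxel threshold, component labeling, extent filtering."""
    t_crit = stats.t.ppf(1.0 - voxel_p / 2.0, df=stat.df)
    geom = stat.geometry
    supra = np.zeros(geom.shape, dtype=bool)
    supra.ravel()[geom.indices] = np.abs(stat.t_values) > t_crit
    structure = connectivity_structure(connectivity)
    labeled, n_comp = ndimage.label(supra, structure=structure)
    comp_of_voxel = labeled.ravel()[geom.indices]
    clusters: list[Cluster] = []
    for comp in range(1, n_comp + 1):
        members = np.flatnonzero(comp_of_voxel == comp)
        if members.size < threshold_size:
            continue
        tvals = stat.t_values[members]
        peak_local = members[np.argmax(np.abs(tvals))]
        peak_ijk = np.unravel_index(geom.indices[peak_local], geom.shape)
        clusters.append(Cluster(voxel_indices=members,
                                size=int(members.size),
                                peak_t=float(stat.t_values[peak_local]),
                                peak_ijk=tuple(int(x) for x in peak_ijk)))
    clusters.sort(key=lambda cl: cl.size, reverse=True)
    return ClusterTable(clusters=clusters,
                        cluster_threshold_size=int(threshold_size),
                        voxel_p_threshold=voxel_p)
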