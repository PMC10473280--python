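"""Voxel-level thresholded connectivity graphs and weighted-degree maps.

The subject-level scoring: Pearson correlations between all in-mask voxel
pairs, one-sided (positive-tail) link p-values, Benjamini-Hochberg FDR across
all upper-triangle links jointly (default q < 0.005), removal of negative
correlations, Fisher r-to-z on the surviving links, and per-voxel weighted
degree (WD) — the sum of a voxel's retained z-weights to the rest of the
brain.

Correlations are computed blockwise so peak memory stays O(block x voxels);
the full dense voxel x voxel matrix is never materialized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .io import BoldSeries, ConfigurationError, MaskGeometry, SchemaError

logger = logging.getLogger("wdhub")

R_CLIP = 1.0 - 1e-7
DEFAULT_Q = 0.005
DEFAULT_BLOCK_SIZE = 2048


@dataclass
class ConnectivityGraph:
    """Sparse symmetric nonnegative z-weighted voxel graph."""

    weights: sp.csr_matrix           # Fisher-z weights, zero diagonal
    n_timepoints_effective: int      # frames used for link p-values
    q_threshold: float
    geometry: MaskGeometry | None = None

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        return self.weights.nnz // 2

    def validate(self) -> None:
        w = self.weights
        if (w != w.T).nnz != 0:
            raise SchemaError("graph weights are not symmetric")
        if w.diagonal().any():
            raise SchemaError("graph diagonal is not zero")
        if w.nnz and w.data.min() <= 0:
            raise SchemaError("graph stores non-positive weights")


@dataclass
class WDMap:
    """Per-voxel weighted-degree centrality map."""

    values: np.ndarray
    flavor: str                      # total | segregated | integrated
    geometry: MaskGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.flavor not in ("total", "segregated", "integrated"):
            raise ConfigurationError(f"unknown WD flavor {self.flavor!r}")
        if self.values.ndim != 1 or np.any(self.values < 0):
            raise SchemaError("WD values must be a nonnegative vector")

    def to_volume(self) -> np.ndarray:
        if self.geometry is None:
            raise SchemaError("WD map carries no geometry")
        return self.geometry.to_volume(self.values)


# ---------------------------------------------------------------------------
# Correlation, blockwise
# ---------------------------------------------------------------------------

def _standardize_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean rows and scale to unit norm; zero-variance rows zeroed and flagged."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    valid = norms > 0
    if not valid.all():
        logger.warning("excluding %d zero-variance voxels from the graph",
                       int((~valid).sum()))
    scale = np.where(valid, norms, 1.0)
    return centered / scale[:, None], valid


def iter_correlation_blocks(series: BoldSeries,
                            block_size: int = DEFAULT_BLOCK_SIZE):
    """Yield ``(start, stop, r_rows)`` with the Pearson rows for a voxel block.

    Zero-variance voxels are excluded (their correlations are reported as 0).
    """
    if series.n_timepoints < 3:
        raise SchemaError("need at least 3 timepoints for correlation")
    X, _valid = _standardize_rows(series.data)
    n = series.n_voxels
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        yield start, stop, X[start:stop] @ X.T


def correlation_matrix(series: BoldSeries,
                       block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
    """Full Pearson matrix, assembled from blocks. For desk-scale problems."""
    n = series.n_voxels
    r = np.empty((n, n))
    for start, stop, rows in iter_correlation_blocks(series, block_size):
        r[start:stop] = rows
    return r


# ---------------------------------------------------------------------------
# Fisher transform and FDR
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); |r| >= 1 is clipped with a warning."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("correlations with |r| >= 1 clipped before atanh",
                      RuntimeWarning, stacklevel=2)
        arr = np.clip(arr, -R_CLIP, R_CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def fdr_threshold(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns indices of retained hypotheses.

    Sort p ascending, find the largest k with p_(k) <= k*q/m, retain those k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=np.int64)
    if np.any((p < 0) | (p > 1)):
        raise SchemaError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ConfigurationError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    passed = p[order] <= q * np.arange(1, m + 1) / m
    if not passed.any():
        return np.array([], dtype=np.int64)
    k = int(np.flatnonzero(passed)[-1]) + 1
    return np.sort(order[:k])


def link_p_values(r: np.ndarray, n_effective: int,
                  two_sided: bool = False) -> np.ndarray:
    """Parametric link p-values from t = r*sqrt((n-2)/(1-r^2))."""
    if n_effective < 3:
        raise SchemaError("need n_effective >= 3 for link p-values")
    rc = np.clip(r, -R_CLIP, R_CLIP)
    t = rc * np.sqrt((n_effective - 2) / (1.0 - rc ** 2))
    if two_sided:
        return 2.0 * stats.t.sf(np.abs(t), df=n_effective - 2)
    return stats.t.sf(t, df=n_effective - 2)


# ---------------------------------------------------------------------------
# Weighted degree
# ---------------------------------------------------------------------------

def weighted_degree(graph: ConnectivityGraph) -> WDMap:
    """WD(v) = sum of v's retained z-weights (sparse row sums)."""
    values = np.asarray(graph.weights.sum(axis=1)).ravel()
    return WDMap(values=values, flavor="total", geometry=graph.geometry)


# ---------------------------------------------------------------------------
# Subject-level graph construction
# ---------------------------------------------------------------------------

def _r_at_p(p: float, n_effective: int) -> float:
    """Correlation whose one-sided (positive-tail) p-value equals ``p``."""
    df = n_effective - 2
    t_val = stats.t.isf(p, df=df)
    return float(t_val / np.sqrt(df + t_val ** 2))


def bh_r_cutoff(r_upper: np.ndarray, q: float, n_effective: int,
                two_sided: bool = False) -> tuple[int, float]:
    """BH step-up retention count and correlation cutoff, computed in r-space.

    One-sided link p-values are a strictly decreasing function of r, so the
    step-up count k* = max{k : p_(k) <= k q / m} is the largest fixed point of
    k -> #{p <= k q / m}, reached by iterating downward from k = m (each
    threshold maps to a correlation cutoff through the inverse t CDF). This
    is algebraically identical to running :func:`fdr_threshold` on the full
    p-vector, without materializing it. Returns ``(k*, r_crit)``: the links
    retained are those with (|r| if two-sided else r) >= r_crit; if k* is 0,
    r_crit is inf.
    """
    m = r_upper.size
    if m == 0:
        return 0, np.inf
    key = np.abs(r_upper) if two_sided else r_upper
    key_sorted = np.sort(key)           # ascending
    halve = 2.0 if two_sided else 1.0
    k = m
    while True:
        r_c = _r_at_p(min(1.0, k * q / m) / halve, n_effective)
        k_new = m - int(np.searchsorted(key_sorted, r_c, side="left"))
        if k_new >= k:
            return k, float(key_sorted[m - k])
        k = k_new
        if k == 0:
            return 0, np.inf


def build_subject_graph(series: BoldSeries, q: float = DEFAULT_Q,
                        n_effective: int | None = None,
                        two_sided: bool = False,
                        block_size: int = DEFAULT_BLOCK_SIZE
                        ) -> tuple[ConnectivityGraph, WDMap]:
    """Correlate -> link p -> BH-FDR -> drop negatives -> Fisher z -> WD.

    ``n_effective`` defaults to the number of frames (interpolated frames are
    counted); pass the censored count to use scrubbed degrees of freedom
    instead. FDR is applied jointly across all upper-triangle in-mask links;
    the step-up cutoff is evaluated in r-space (see :func:`bh_r_cutoff`),
    which is exactly equivalent to BH on the link p-values.
    """
    n = series.n_voxels
    if n_effective is None:
        n_effective = series.n_timepoints
    if not 0 < q < 1:
        raise ConfigurationError("q must lie in (0, 1)")
    # canonical row-major upper-triangle order, assembled block by block
    r_parts = []
    for start, stop, rows in iter_correlation_blocks(series, block_size):
        for i in range(start, stop):
            r_parts.append(rows[i - start, i + 1:])
    r_upper = np.concatenate(r_parts) if r_parts else np.empty(0)

    k_star, r_crit = bh_r_cutoff(r_upper, q, n_effective, two_sided=two_sided)
    if k_star > 0:
        key = np.abs(r_upper) if two_sided else r_upper
        retained = np.flatnonzero((key >= r_crit) & (r_upper > 0))
    else:
        retained = np.array([], dtype=np.int64)

    rows_idx, cols_idx = np.triu_indices(n, k=1)
    i_idx = rows_idx[retained]
    j_idx = cols_idx[retained]
    z = fisher_z(np.clip(r_upper[retained], -R_CLIP, R_CLIP))

    upper = sp.coo_matrix((z, (i_idx, j_idx)), shape=(n, n))
    weights = (upper + upper.T).tocsr()
    graph = ConnectivityGraph(weights=weights,
                              n_timepoints_effective=int(n_effective),
                              q_threshold=q, geometry=series.geometry)
    logger.info("graph: %d voxels, %d retained links (q=%g)",
                n, graph.n_links, q)
    return graph, weighted_degree(graph)
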