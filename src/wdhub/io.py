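"""Shared containers, NIfTI/TSV/HDF5 readers and writers, configuration.

Conventions used throughout the package:

* volumes are written float32 (labels/masks as integers) and computed float64;
* affines are RAS with explicit voxel sizes;
* in-mask voxels are ordered by ascending linear index under C array layout,
  and every per-voxel vector in the package follows that ordering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

logger = logging.getLogger("wdhub")

MOTION_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_x_rad", "rot_y_rad", "rot_z_rad",
]


class WDHubError(Exception):
    """Base class for package errors."""


class ConfigurationError(WDHubError, ValueError):
    """An input configuration violates a stated invariant."""


class SchemaError(WDHubError, ValueError):
    """A table or array does not have the expected columns/shape."""


class ModelError(WDHubError, ValueError):
    """A statistical design is unusable (e.g. rank deficient)."""


class DataQualityError(WDHubError, ValueError):
    """The data cannot support the requested operation (e.g. all frames flagged)."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class MaskGeometry:
    """Voxel grid shape, affine, and linear indices of in-mask voxels."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    indices: np.ndarray  # ascending linear indices (C order) of in-mask voxels

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if np.any(np.diff(self.indices) <= 0):
            raise ConfigurationError("mask indices must be strictly ascending")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def mask_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol.ravel()[self.indices] = True
        return vol

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Project a per-mask-voxel vector back into a 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise SchemaError(
                f"expected {self.n_voxels} voxel values, got shape {values.shape}")
        vol = np.full(self.shape, fill, dtype=float)
        vol.ravel()[self.indices] = values
        return vol

    def ijk(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates of in-mask voxels."""
        return np.column_stack(np.unravel_index(self.indices, self.shape))


@dataclass
class BoldSeries:
    """Masked voxel x time matrix for one subject."""

    data: np.ndarray  # (n_voxels, n_timepoints) float64
    geometry: MaskGeometry
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SchemaError("BOLD data must be a 2D voxel x time matrix")
        if self.data.shape[0] != self.geometry.n_voxels:
            raise SchemaError(
                f"{self.data.shape[0]} rows but {self.geometry.n_voxels} mask voxels")
        if not np.all(np.isfinite(self.data)):
            raise DataQualityError("BOLD series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data=data, geometry=self.geometry,
                          tr_seconds=self.tr_seconds)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def write_nifti(path: str | Path, volume: np.ndarray, affine: np.ndarray,
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(volume).astype(dtype), np.asarray(affine))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_bold(path: str | Path, series: BoldSeries) -> None:
    """Write a masked series as a 4D volume (zeros outside the mask)."""
    geom = series.geometry
    vol4d = np.zeros(geom.shape + (series.n_timepoints,), dtype=np.float32)
    flat = vol4d.reshape(-1, series.n_timepoints)
    flat[geom.indices] = series.data.astype(np.float32)
    write_nifti(path, vol4d, geom.affine)


def read_bold(bold_path: str | Path, mask_path: str | Path,
              tr_seconds: float) -> BoldSeries:
    data4d, affine = read_nifti(bold_path)
    if data4d.ndim != 4:
        raise SchemaError(f"{bold_path}: expected 4D BOLD, got {data4d.ndim}D")
    mask, mask_affine = read_nifti(mask_path)
    if mask.shape != data4d.shape[:3]:
        raise SchemaError("mask and BOLD grids differ")
    geom = MaskGeometry(shape=mask.shape, affine=affine,
                        indices=np.flatnonzero(mask.ravel() > 0))
    flat = data4d.reshape(-1, data4d.shape[3])
    return BoldSeries(data=flat[geom.indices].astype(float), geometry=geom,
                      tr_seconds=tr_seconds)


def read_mask(path: str | Path) -> MaskGeometry:
    mask, affine = read_nifti(path)
    return MaskGeometry(shape=mask.shape, affine=affine,
                        indices=np.flatnonzero(mask.ravel() > 0))


def read_labels(path: str | Path, geometry: MaskGeometry) -> np.ndarray:
    """Integer community label per in-mask voxel from a label volume."""
    vol, _ = read_nifti(path)
    if vol.shape != tuple(geometry.shape):
        raise SchemaError("label volume grid does not match the mask grid")
    labels = np.rint(vol.ravel()[geometry.indices]).astype(int)
    return labels


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column motion table (mm translations, rad rotations)."""
    frame = read_tsv(path)
    missing = [c for c in MOTION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"motion table missing columns {missing}")
    return frame[MOTION_COLUMNS].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Sparse graph round-trip (HDF5: row, col, weight, n_voxels)
# ---------------------------------------------------------------------------

def write_graph_h5(path: str | Path, weights: sp.spmatrix,
                   attrs: dict | None = None) -> None:
    coo = sp.triu(weights.tocoo(), k=1)
    with h5py.File(str(path), "w") as f:
        f.create_dataset("row", data=coo.row.astype(np.int64))
        f.create_dataset("col", data=coo.col.astype(np.int64))
        f.create_dataset("weight", data=coo.data.astype(np.float64))
        f.attrs["n_voxels"] = weights.shape[0]
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def read_graph_h5(path: str | Path) -> tuple[sp.csr_matrix, dict]:
    with h5py.File(str(path), "r") as f:
        row = f["row"][:]
        col = f["col"][:]
        weight = f["weight"][:]
        n = int(f.attrs["n_voxels"])
        attrs = {k: f.attrs[k] for k in f.attrs if k != "n_voxels"}
    upper = sp.coo_matrix((weight, (row, col)), shape=(n, n))
    return (upper + upper.T).tocsr(), attrs


# ---------------------------------------------------------------------------
# Pipeline configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage parameters; the defaults are the reference analysis settings.

    The voxel-forming threshold for cluster inference defaults to a strict
    two-tailed p = 0.005: at liberal primary thresholds, cluster-extent
    correction against Gaussian-matched nulls is known to be anticonservative
    (the extent null underestimates the large clusters formed by diffuse
    low-amplitude fields), whereas strict thresholds keep the family-wise
    error of the extent test accurate. The cluster-level alpha stays 0.05.
    """

    q_threshold: float = 0.005        # BH-FDR level for link retention
    fd_threshold_mm: float = 0.2      # scrubbing threshold on Jenkinson FD
    fd_radius_mm: float = 80.0        # head-sphere radius for FD
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fwhm_mm: float = 6.0              # spatial smoothing kernel
    n_iter: int = 10000               # Monte-Carlo null iterations
    voxel_p: float = 0.005            # two-tailed voxel-forming threshold
    cluster_connectivity: int = 26    # 6, 18, or 26
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ConfigurationError("q_threshold must lie in (0, 1)")
        if not 0 <= self.band_low_hz < self.band_high_hz:
            raise ConfigurationError("band limits must satisfy 0 <= low < high")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ConfigurationError("cluster_connectivity must be 6, 18 or 26")
        if self.fwhm_mm <= 0 or self.fd_threshold_mm <= 0:
            raise ConfigurationError("fwhm_mm and fd_threshold_mm must be positive")
        if self.n_iter < 1 or not 0 < self.voxel_p <= 1:
            raise ConfigurationError("n_iter >= 1 and voxel_p in (0, 1] required")

    def hash(self) -> str:
        """Stable content hash (invariant to key order in YAML sources)."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def provenance_record(config: PipelineConfig, **extra) -> dict:
    from wdhub import __version__
    rec = {"version": __version__, "config_hash": config.hash(),
           "config": asdict(config)}
    rec.update(extra)
    return rec


def write_provenance(path: str | Path, record: dict) -> None:
    with open(path, "w") as f:
        json.dump(record, f, indent=2, sort_keys=True, default=str)
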