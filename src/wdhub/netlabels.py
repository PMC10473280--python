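"""Segregated/integrated decomposition of weighted degree.

Given a voxel parcellation into functional communities, each retained link is
classified by its endpoints: same community -> segregated link, different
communities -> integrated link. Summing z-weights separately over the two
link classes yields two per-voxel maps that partition total weighted degree
exactly: WD_seg(v) + WD_int(v) = WD_total(v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .connectivity import ConnectivityGraph, WDMap
from .io import SchemaError


class LabelingError(SchemaError):
    """A graph voxel has no usable community label."""


@dataclass
class Parcellation:
    """Community index (1..K) per mask voxel, plus optional names."""

    labels: np.ndarray
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise SchemaError("labels must be a per-voxel vector")

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels[self.labels > 0]).size)

    def check_covers(self, n_voxels: int) -> None:
        if self.labels.size != n_voxels:
            raise LabelingError(
                f"parcellation labels {self.labels.size} voxels "
                f"but the graph has {n_voxels}")
        bad = np.flatnonzero(self.labels <= 0)
        if bad.size:
            raise LabelingError(
                f"{bad.size} graph voxels lack a positive community label "
                f"(first offenders: {bad[:10].tolist()})")


def _upper_links(graph: ConnectivityGraph) -> sp.coo_matrix:
    return sp.triu(graph.weights.tocoo(), k=1).tocoo()


def classify_links(graph: ConnectivityGraph, parcellation: Parcellation
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Partition retained links into (segregated, integrated) endpoint pairs.

    Returns two integer arrays of shape (n_links_in_class, 2); together they
    partition the upper-triangle link set exhaustively and disjointly.
    """
    parcellation.check_covers(graph.n_voxels)
    coo = _upper_links(graph)
    same = parcellation.labels[coo.row] == parcellation.labels[coo.col]
    seg = np.column_stack([coo.row[same], coo.col[same]])
    integ = np.column_stack([coo.row[~same], coo.col[~same]])
    return seg, integ


def decomposed_wd(graph: ConnectivityGraph, parcellation: Parcellation
                  ) -> tuple[WDMap, WDMap]:
    """Per-voxel WD over segregated and over integrated links."""
    parcellation.check_covers(graph.n_voxels)
    coo = _upper_links(graph)
    same = parcellation.labels[coo.row] == parcellation.labels[coo.col]
    n = graph.n_voxels
    seg = np.zeros(n)
    integ = np.zeros(n)
    for mask, acc in ((same, seg), (~same, integ)):
        acc += np.bincount(coo.row[mask], weights=coo.data[mask], minlength=n)
        acc += np.bincount(coo.col[mask], weights=coo.data[mask], minlength=n)
    return (WDMap(values=seg, flavor="segregated", geometry=graph.geometry),
            WDMap(values=integ, flavor="integrated", geometry=graph.geometry))
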