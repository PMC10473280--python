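"""End-to-end orchestration: simulate -> preprocess -> connect -> decompose ->
GLM -> Monte-Carlo cluster correction, with provenance.

The in-memory entry points (:func:`process_subject`,
:func:`subject_wd_maps`, :func:`analyze_cohort`) are the working surface for
scripted analyses and tests; :func:`run_pipeline` is the disk-based variant
behind the command line, reading and writing NIfTI/TSV/JSON artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from .connectivity import WDMap, build_subject_graph
from .inference import (ClusterNull, ClusterTable, SmoothnessEstimate, StatMap,
                        apply_cluster_correction, cluster_null,
                        estimate_smoothness, glm_map, group_design,
                        covariate_design, standardize_maps)
from .io import (BoldSeries, MaskGeometry, PipelineConfig, provenance_record,
                 read_bold, read_labels, read_mask, read_motion, read_tsv,
                 write_nifti, write_provenance, write_tsv)
from .netlabels import Parcellation, decomposed_wd
from .preprocess import preprocess_series
from .synthgen import SimConfig, simulate_cohort_arrays

logger = logging.getLogger("wdhub")

WD_FLAVORS = ("total", "segregated", "integrated")


def process_subject(series: BoldSeries, motion, nuisance,
                    config: PipelineConfig):
    """Preprocess one subject's series under the pipeline configuration."""
    return preprocess_series(
        series, motion, nuisance,
        fd_threshold_mm=config.fd_threshold_mm,
        fd_radius_mm=config.fd_radius_mm,
        band=(config.band_low_hz, config.band_high_hz),
        fwhm_mm=config.fwhm_mm)


def subject_wd_maps(series: BoldSeries, parcellation: Parcellation,
                    config: PipelineConfig) -> dict[str, WDMap]:
    """Thresholded graph plus total/segregated/integrated WD maps."""
    graph, wd_total = build_subject_graph(series, q=config.q_threshold)
    wd_seg, wd_int = decomposed_wd(graph, parcellation)
    return {"total": wd_total, "segregated": wd_seg, "integrated": wd_int}


@dataclass
class GroupResult:
    stat: StatMap
    smoothness: SmoothnessEstimate
    null: ClusterNull
    clusters: ClusterTable


@dataclass
class CohortAnalysis:
    """Everything the group stage produces, per WD flavor."""

    geometry: MaskGeometry
    groups: list[str]
    wd: dict[str, np.ndarray]                  # flavor -> subjects x voxels
    results: dict[str, GroupResult] = field(default_factory=dict)


def cohort_wd_matrices(subjects, parcellation: Parcellation,
                       config: PipelineConfig) -> CohortAnalysis:
    """Per-subject pipeline over a cohort; stacks WD maps per flavor.

    ``subjects`` is an iterable of (subject_id, group, BoldSeries, motion_df,
    nuisance_df) records as produced by the synthetic cohort generator.
    """
    rows: dict[str, list[np.ndarray]] = {f: [] for f in WD_FLAVORS}
    groups: list[str] = []
    geometry = None
    for sid, group, series, motion, nuisance in subjects:
        clean, _summary = process_subject(series, motion, nuisance, config)
        maps = subject_wd_maps(clean, parcellation, config)
        for flavor in WD_FLAVORS:
            rows[flavor].append(maps[flavor].values)
        groups.append(group)
        geometry = series.geometry
        logger.info("subject %s (%s): WD computed", sid, group)
    wd = {f: np.vstack(rows[f]) for f in WD_FLAVORS}
    return CohortAnalysis(geometry=geometry, groups=groups, wd=wd)


def group_contrast(wd_matrix: np.ndarray, groups, geometry: MaskGeometry,
                   config: PipelineConfig, positive: str = "A",
                   n_iter: int | None = None,
                   seed: int | np.random.Generator | None = None,
                   standardize: bool = True,
                   contrast_name: str = "group A-B") -> GroupResult:
    """Two-group GLM with Monte-Carlo cluster-extent correction.

    By default each subject's map is z-scored across voxels first (see
    :func:`wdhub.inference.standardize_maps`).
    """
    X, c = group_design(np.asarray(groups), positive=positive)
    Y = standardize_maps(wd_matrix) if standardize else wd_matrix
    stat, resid = glm_map(Y, X, c, geometry, contrast_name=contrast_name)
    smooth = estimate_smoothness(resid, geometry)
    null = cluster_null(smooth, geometry, voxel_p=config.voxel_p,
                        n_iter=n_iter or config.n_iter,
                        seed=config.seed if seed is None else seed,
                        connectivity=config.cluster_connectivity)
    table = apply_cluster_correction(stat, null.threshold_size,
                                     voxel_p=config.voxel_p,
                                     connectivity=config.cluster_connectivity)
    return GroupResult(stat=stat, smoothness=smooth, null=null,
                       clusters=table)


def covariate_contrast(wd_matrix: np.ndarray, covariate: np.ndarray,
                       geometry: MaskGeometry, config: PipelineConfig,
                       n_iter: int | None = None,
                       seed: int | np.random.Generator | None = None,
                       standardize: bool = True,
                       contrast_name: str = "covariate slope") -> GroupResult:
    """Within-group brain-behavior GLM with cluster correction."""
    X, c = covariate_design(covariate)
    Y = standardize_maps(wd_matrix) if standardize else wd_matrix
    stat, resid = glm_map(Y, X, c, geometry, contrast_name=contrast_name)
    smooth = estimate_smoothness(resid, geometry)
    null = cluster_null(smooth, geometry, voxel_p=config.voxel_p,
                        n_iter=n_iter or config.n_iter,
                        seed=config.seed if seed is None else seed,
                        connectivity=config.cluster_connectivity)
    table = apply_cluster_correction(stat, null.threshold_size,
                                     voxel_p=config.voxel_p,
                                     connectivity=config.cluster_connectivity)
    return GroupResult(stat=stat, smoothness=smooth, null=null,
                       clusters=table)


def analyze_cohort(sim_config: SimConfig, n_per_group: int,
                   config: PipelineConfig,
                   n_iter: int | None = None,
                   flavors=WD_FLAVORS):
    """Simulate a cohort in memory and run the full analysis.

    Returns ``(CohortAnalysis, GroundTruth, behavioral_table)`` with one
    :class:`GroupResult` per requested WD flavor. Null-simulation seeds derive
    from the simulation seed, so a rerun with the same configuration is
    bit-identical.
    """
    subjects, truth, behavioral = simulate_cohort_arrays(sim_config,
                                                         n_per_group)
    parcellation = Parcellation(labels=truth.labels)
    analysis = cohort_wd_matrices(subjects, parcellation, config)
    null_rng = np.random.default_rng(
        np.random.default_rng(sim_config.seed).integers(0, 2 ** 31))
    for flavor in flavors:
        analysis.results[flavor] = group_contrast(
            analysis.wd[flavor], analysis.groups, analysis.geometry, config,
            n_iter=n_iter, seed=null_rng,
            contrast_name=f"group A-B ({flavor} WD)")
    return analysis, truth, behavioral


def dice_coefficient(indices_a: np.ndarray, indices_b: np.ndarray) -> float:
    """Dice overlap between two voxel index sets."""
    a = np.unique(np.asarray(indices_a))
    b = np.unique(np.asarray(indices_b))
    if a.size == 0 and b.size == 0:
        return 1.0
    inter = np.intersect1d(a, b).size
    return 2.0 * inter / (a.size + b.size)


# ---------------------------------------------------------------------------
# Disk-based pipeline (CLI back end)
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, sim_config: SimConfig,
                 n_per_group: int, out_dir: str | Path,
                 n_iter: int | None = None) -> Path:
    """simulate -> preprocess -> connect -> decompose -> glm -> correct.

    Writes the cohort, per-flavor group t-maps, cluster-labeled volumes,
    cluster tables, the behavioral report, and a provenance JSON stamped with
    the configuration hash. Deterministic for a fixed configuration.
    """
    from .synthgen import simulate_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = out / "cohort"
    truth = simulate_cohort(sim_config, n_per_group, cohort_dir)

    geometry = read_mask(cohort_dir / "mask.nii.gz")
    labels = read_labels(cohort_dir / "labels.nii.gz", geometry)
    parcellation = Parcellation(labels=labels)

    subjects = []
    for sid in sorted(truth.group_assignment):
        series = read_bold(cohort_dir / f"{sid}_bold.nii.gz",
                           cohort_dir / "mask.nii.gz",
                           tr_seconds=sim_config.tr_seconds)
        motion = read_motion(cohort_dir / f"{sid}_motion.tsv")
        nuisance = read_tsv(cohort_dir / f"{sid}_nuisance.tsv")
        subjects.append((sid, truth.group_assignment[sid], series,
                         motion, nuisance))

    analysis = cohort_wd_matrices(subjects, parcellation, config)
    null_rng = np.random.default_rng(config.seed)
    cluster_counts = {}
    for flavor in WD_FLAVORS:
        res = group_contrast(analysis.wd[flavor], analysis.groups,
                             analysis.geometry, config, n_iter=n_iter,
                             seed=null_rng,
                             contrast_name=f"group A-B ({flavor} WD)")
        analysis.results[flavor] = res
        write_nifti(out / f"tmap_{flavor}.nii.gz",
                    analysis.geometry.to_volume(res.stat.t_values),
                    analysis.geometry.affine)
        label_vol = np.zeros(analysis.geometry.shape)
        for k, cl in enumerate(res.clusters, start=1):
            label_vol.ravel()[analysis.geometry.indices[cl.voxel_indices]] = k
        write_nifti(out / f"clusters_{flavor}.nii.gz", label_vol,
                    analysis.geometry.affine, dtype=np.int16)
        write_tsv(out / f"clusters_{flavor}.tsv",
                  pd.DataFrame(res.clusters.to_records()))
        cluster_counts[flavor] = len(res.clusters)

    scored = bh.score_table(read_tsv(cohort_dir / "behavioral.tsv"))
    report = bh.group_compare_table(scored)
    with open(out / "behavior_report.json", "w") as f:
        json.dump(report.to_dict(), f, indent=2)

    write_provenance(out / "provenance.json", provenance_record(
        config,
        sim_seed=sim_config.seed,
        n_per_group=n_per_group,
        n_iter=n_iter or config.n_iter,
        surviving_clusters=cluster_counts,
        smoothness_fwhm_mm={f: analysis.results[f].smoothness.fwhm_mm.tolist()
                            for f in WD_FLAVORS},
    ))
    logger.info("pipeline complete: %s", out)
    return out
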