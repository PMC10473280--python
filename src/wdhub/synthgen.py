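"""Synthetic multi-subject resting-state BOLD with planted group effects.

The generator emulates the statistical structure a voxel-level hub analysis
consumes: community-structured correlations among gray-matter voxels, a
group-specific reduction of one community's between-network coupling, head
motion traces with occasional spikes, nuisance component tables, and a
behavioral table whose vividness composite tracks each subject's planted
coupling reduction.

Correlation model
-----------------
Every voxel in community ``c`` is a mixture of one community latent, one
global latent shared by all communities, and voxel-private noise::

    x_i(t) = sqrt(a_c) * L_c(t) + sqrt(b_c) * G(t) + noise_sd * e_i(t)

Latents (community and global) are slow band-limited signals, exactly
orthonormal in sample (see ``_orthonormal_latents``); voxel noise is
broadband (an AR(1), coefficient 0.3, plus white noise mixture). The
loadings solve the correlation targets:

    total voxel variance  v = noise_sd^2 / (1 - within_r)
    b_c = between_r * v,   a_c = (within_r - between_r) * v

For a subject whose effect community has its between-network coupling
reduced by ``delta``, that community's global loading is re-solved so its
cross-community correlation equals ``between_r - delta`` while its
within-community correlation stays at ``within_r`` — the planted effect is
purely "integrated" (between-network), never "segregated".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import (BoldSeries, ConfigurationError, MaskGeometry, MOTION_COLUMNS,
                 write_bold, write_nifti, write_tsv)

AR_COEF = 0.3         # temporal autocorrelation of voxel noise
AR_MIX = 0.5          # variance fraction of the AR(1) part (rest is white)
LATENT_BAND_HZ = (0.01, 0.08)  # canonical resting-state fluctuation band
DELTA_JITTER_SD = 0.04  # between-subject spread of the planted coupling reduction
VIVID_BASE = 60.0     # behavioral composite at zero coupling reduction
VIVID_NOISE_SD = 4.0  # subject-level noise on the composite
ITEM_NOISE_SD = 3.0   # item-level noise around the composite

NUISANCE_COLUMNS = [f"ventricle_pc{i}" for i in range(1, 6)] + \
                   [f"wm_pc{i}" for i in range(1, 6)]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are desk-scale: a 12x12x12 grid of 3-mm voxels standing in for
    the ~39k-voxel gray-matter sheet, five compact contiguous block
    communities standing in for a resting-state network parcellation, TR
    matching a typical multiband acquisition, and a between-network coupling
    reduction planted in one community for group A.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 6.0
    tr_seconds: float = 1.5
    n_timepoints: int = 400
    n_communities: int = 5
    within_r: float = 0.5
    between_r: float = 0.2
    effect_community: int = 1          # 1-based community index
    effect_delta: float = 0.15         # reduction of between_r in group A
    noise_sd: float = 1.0
    motion_spike_prob: float = 0.02
    behavioral_slope: float = -1.0     # composite points per % coupling reduction
    within_r_subject_sd: float = 0.0   # between-subject spread of within_r
    between_r_subject_sd: float = 0.0  # between-subject spread of between_r
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 axes, each >= 4")
        if not 0 <= self.within_r < 1:
            raise ConfigurationError("within_r must lie in [0, 1)")
        if not 0 <= self.between_r < self.within_r:
            raise ConfigurationError("between_r must lie in [0, within_r)")
        if not 0 <= self.effect_delta <= self.between_r:
            raise ConfigurationError("effect_delta must lie in [0, between_r]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must not be negative")
        if self.within_r_subject_sd < 0 or self.between_r_subject_sd < 0:
            raise ConfigurationError("subject coupling spreads must be >= 0")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ConfigurationError("motion_spike_prob must lie in [0, 1]")
        if self.n_timepoints < 3 or self.tr_seconds <= 0:
            raise ConfigurationError("need n_timepoints >= 3 and tr_seconds > 0")
        if not 1 <= self.effect_community <= self.n_communities:
            raise ConfigurationError(
                "effect_community must name one of the n_communities communities")

    def geometry(self) -> MaskGeometry:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        n = int(np.prod(self.grid_shape))
        return MaskGeometry(shape=self.grid_shape, affine=affine,
                            indices=np.arange(n))

    def labels(self) -> np.ndarray:
        """Community index (1..K) per mask voxel.

        Communities are compact contiguous 3D blocks produced by recursive
        bisection (each split halves the longest axis, allocating cells in
        proportion to the communities assigned to each side). Compact blocks
        keep most community voxels away from community borders, so spatial
        smoothing at a realistic kernel width does not erase the community
        structure the way thin slabs would.
        """
        vol = np.zeros(self.grid_shape, dtype=int)
        _bisect_labels(vol, tuple(slice(0, s) for s in self.grid_shape),
                       1, self.n_communities)
        if np.any(vol <= 0):
            raise ConfigurationError(
                "grid too small to partition into that many communities")
        return vol.ravel().copy()


def _bisect_labels(vol: np.ndarray, region: tuple[slice, slice, slice],
                   first_label: int, n_parts: int) -> None:
    """Assign labels first_label..first_label+n_parts-1 to a grid region."""
    if n_parts == 1:
        vol[region] = first_label
        return
    sizes = [r.stop - r.start for r in region]
    axis = int(np.argmax(sizes))
    left_parts = n_parts // 2
    cut = region[axis].start + int(round(sizes[axis] * left_parts / n_parts))
    cut = min(max(cut, region[axis].start + 1), region[axis].stop - 1)
    left = list(region)
    right = list(region)
    left[axis] = slice(region[axis].start, cut)
    right[axis] = slice(cut, region[axis].stop)
    _bisect_labels(vol, tuple(left), first_label, left_parts)
    _bisect_labels(vol, tuple(right), first_label + left_parts,
                   n_parts - left_parts)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    labels: np.ndarray                    # community per mask voxel
    group_assignment: dict[str, str]      # subject_id -> "A" | "B"
    true_effect_voxels: np.ndarray        # mask-voxel indices carrying the effect
    behavioral_slope: float
    subject_delta: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Time-series sources
# ---------------------------------------------------------------------------

def _unit_sources(rng: np.random.Generator, n_sources: int,
                  n_timepoints: int) -> np.ndarray:
    """Unit-variance sources with an AR(1)+white spectrum, one per row."""
    white = rng.standard_normal((n_sources, n_timepoints))
    innov = rng.standard_normal((n_sources, n_timepoints))
    ar = lfilter([np.sqrt(1.0 - AR_COEF ** 2)], [1.0, -AR_COEF], innov, axis=1)
    return np.sqrt(AR_MIX) * ar + np.sqrt(1.0 - AR_MIX) * white


def _orthonormal_latents(rng: np.random.Generator, n_sources: int,
                         n_timepoints: int, tr_seconds: float) -> np.ndarray:
    """Band-limited latent network signals, exactly uncorrelated in sample.

    Network fluctuations in resting BOLD are slow; latents are generated with
    spectral support in the canonical low-frequency band, then
    sample-orthonormalized (QR) so that every latent has unit sample variance
    and exactly zero sample correlation with every other latent. This makes
    the realized community coupling structure equal to its analytic targets
    rather than merely converging to them, so the planted group effect is the
    only block-level difference between subjects.
    """
    white = rng.standard_normal((n_sources, n_timepoints))
    spect = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    keep = (freqs >= LATENT_BAND_HZ[0]) & (freqs <= LATENT_BAND_HZ[1])
    if keep.sum() < n_sources:
        # very short series: fall back to broadband sources
        keep = freqs > 0
    spect[:, ~keep] = 0.0
    band = np.fft.irfft(spect, n=n_timepoints, axis=1)
    band -= band.mean(axis=1, keepdims=True)
    q, r = np.linalg.qr(band.T)                 # T x n_sources
    q *= np.sign(np.diag(r))                    # fix the QR sign ambiguity
    return q.T * np.sqrt(n_timepoints - 1)


def _community_loadings(n_communities: int, effect_community: int,
                        within_r: float, between_r: float, delta: float,
                        noise_sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-community latent/global variance loadings (a_c, b_c).

    Solved so within-community correlation is within_r for every community and
    the effect community's cross-community correlation is between_r - delta.
    In the degenerate noiseless case (noise_sd = 0) voxel series are pure
    latent mixtures, so within-community correlations are exactly 1.
    """
    v = noise_sd ** 2 / (1.0 - within_r) if noise_sd > 0 else 1.0
    a = np.full(n_communities, (within_r - between_r) * v)
    b = np.full(n_communities, between_r * v)
    if delta > 0 and between_r > 0:
        k = effect_community - 1
        b[k] = v * (between_r - delta) ** 2 / between_r
        a[k] = within_r * v - b[k]
    return a, b


# ---------------------------------------------------------------------------
# Per-subject simulation
# ---------------------------------------------------------------------------

def simulate_subject(config: SimConfig, group: str, subject_seed: int
                     ) -> tuple[BoldSeries, pd.DataFrame, pd.DataFrame, float]:
    """Simulate one subject's BOLD, motion table, and nuisance table.

    Group "A" subjects carry the planted between-network coupling reduction
    of the effect community (with small between-subject jitter); group "B"
    subjects have no planted reduction. Subjects also differ in their overall
    coupling levels: per-subject within/between correlations are drawn around
    the configured targets with the configured spreads, emulating the
    between-subject variability of real cohorts. Returns the realized
    per-subject reduction ``delta`` as the fourth element — the subject's
    effect magnitude used by the behavioral generator.

    A pure function of ``(config, group, subject_seed)``.
    """
    if group not in ("A", "B"):
        raise ConfigurationError(f"group must be 'A' or 'B', got {group!r}")
    rng = np.random.default_rng(subject_seed)
    geom = config.geometry()
    labels = config.labels()
    T = config.n_timepoints

    within_s = float(np.clip(rng.normal(config.within_r,
                                        config.within_r_subject_sd),
                             0.05, 0.95))
    between_s = float(np.clip(rng.normal(config.between_r,
                                         config.between_r_subject_sd),
                             0.0, within_s - 0.02))
    group_delta = config.effect_delta if group == "A" else 0.0
    jitter = DELTA_JITTER_SD if config.effect_delta > 0 else 0.0
    delta = float(np.clip(rng.normal(group_delta, jitter), 0.0, between_s))

    a, b = _community_loadings(config.n_communities, config.effect_community,
                               within_s, between_s, delta, config.noise_sd)
    latents = _orthonormal_latents(rng, config.n_communities + 1, T,
                                   config.tr_seconds)
    community_latents, global_latent = latents[:-1], latents[-1]

    data = config.noise_sd * _unit_sources(rng, geom.n_voxels, T)
    for k in range(config.n_communities):
        rows = labels == k + 1
        data[rows] += (np.sqrt(a[k]) * community_latents[k]
                       + np.sqrt(b[k]) * global_latent)
    data += 1000.0  # arbitrary BOLD-like baseline

    motion = _simulate_motion(rng, T, config.motion_spike_prob)
    nuisance = pd.DataFrame(_unit_sources(rng, len(NUISANCE_COLUMNS), T).T,
                            columns=NUISANCE_COLUMNS)

    series = BoldSeries(data=data, geometry=geom, tr_seconds=config.tr_seconds)
    return series, motion, nuisance, delta


def _simulate_motion(rng: np.random.Generator, n_timepoints: int,
                     spike_prob: float) -> pd.DataFrame:
    """Slow random-walk drift plus occasional one-frame translation spikes."""
    steps = rng.normal(0.0, [[0.01]] * 3 + [[2e-4]] * 3,
                       size=(6, n_timepoints))
    params = np.cumsum(steps, axis=1)
    spikes = rng.random(n_timepoints - 1) < spike_prob
    for t in np.flatnonzero(spikes) + 1:
        axis = rng.integers(0, 3)
        params[axis, t] += rng.uniform(0.3, 0.8) * rng.choice([-1.0, 1.0])
    return pd.DataFrame(params.T, columns=MOTION_COLUMNS)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _behavioral_items(rng: np.random.Generator, delta: float,
                      slope: float) -> list[float]:
    """Four vividness items (1-100); item 4 is difficulty, stored inverted."""
    composite = VIVID_BASE + slope * (100.0 * delta) \
        + rng.normal(0.0, VIVID_NOISE_SD)
    items = np.clip(composite + rng.normal(0.0, ITEM_NOISE_SD, size=4),
                    1.0, 100.0)
    items[3] = np.clip(101.0 - items[3], 1.0, 100.0)  # difficulty, reverse-keyed
    return [float(x) for x in items]


def simulate_cohort_arrays(config: SimConfig, n_per_group: int):
    """In-memory cohort: list of subject records, ground truth, behavior table.

    Each subject record is ``(subject_id, group, BoldSeries, motion_df,
    nuisance_df)``. Per-subject seeds and behavioral noise derive
    deterministically from ``config.seed``.
    """
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    master = np.random.default_rng(config.seed)
    subject_seeds = master.integers(0, 2 ** 31, size=2 * n_per_group)
    behav_rng = np.random.default_rng(master.integers(0, 2 ** 31))

    labels = config.labels()
    truth = GroundTruth(
        labels=labels,
        group_assignment={},
        true_effect_voxels=np.flatnonzero(labels == config.effect_community),
        behavioral_slope=config.behavioral_slope,
    )
    subjects = []
    behav_rows = []
    for i in range(2 * n_per_group):
        group = "A" if i < n_per_group else "B"
        sid = f"sub-{group}{(i % n_per_group) + 1:02d}"
        series, motion, nuisance, delta = simulate_subject(
            config, group, int(subject_seeds[i]))
        truth.group_assignment[sid] = group
        truth.subject_delta[sid] = delta
        subjects.append((sid, group, series, motion, nuisance))
        items = _behavioral_items(behav_rng, delta, config.behavioral_slope)
        behav_rows.append({"subject_id": sid,
                           "group": "expert" if group == "A" else "control",
                           "item1": items[0], "item2": items[1],
                           "item3": items[2], "item4": items[3]})
    behavioral = pd.DataFrame(behav_rows)
    return subjects, truth, behavioral


def simulate_cohort(config: SimConfig, n_per_group: int,
                    out_dir: str | Path) -> GroundTruth:
    """Write a full synthetic cohort to ``out_dir``.

    Produces one 4D BOLD NIfTI plus motion and nuisance TSVs per subject,
    a binary mask, an integer community label volume, and the behavioral
    table. Returns the planted ground truth.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {out} is not writable: {exc}") from exc

    subjects, truth, behavioral = simulate_cohort_arrays(config, n_per_group)
    geom = config.geometry()

    write_nifti(out / "mask.nii.gz",
                geom.mask_volume().astype(np.int16), geom.affine,
                dtype=np.int16)
    write_nifti(out / "labels.nii.gz",
                geom.to_volume(truth.labels.astype(float)), geom.affine,
                dtype=np.int16)
    for sid, _group, series, motion, nuisance in subjects:
        write_bold(out / f"{sid}_bold.nii.gz", series)
        write_tsv(out / f"{sid}_motion.tsv", motion)
        write_tsv(out / f"{sid}_nuisance.tsv", nuisance)
    write_tsv(out / "behavioral.tsv", behavioral)
    return truth
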