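# wdhub

Voxel-level **weighted-degree (WD) hub analysis** of resting-state fMRI:
per-subject thresholded functional connectivity graphs, WD centrality maps
with a segregated/integrated decomposition against a network parcellation,
and group-level inference with Monte-Carlo cluster-extent correction —
together with a synthetic multi-subject BOLD generator that plants known
group effects so the whole chain can be validated against ground truth.

## Who this is for

Researchers studying individual or group differences in whole-brain
functional network organization — for example, comparing a cohort of
creative experts against matched controls — who want a voxel-level,
parcellation-light hub analysis with every statistical step testable.

## The method

For each subject, after standard post-registration preprocessing
(confound regression, motion scrubbing, band-pass filtering, spatial
smoothing):

1. **Connectivity.** Pearson correlations r(i,j) between all pairs of
   in-mask voxel time series, computed blockwise.
2. **Thresholding.** One-sided (positive-tail) link p-values from
   t = r·√((n−2)/(1−r²)) are screened with Benjamini–Hochberg FDR at
   q < 0.005 jointly across all links; negative correlations are removed;
   surviving links are weighted by the Fisher transform z = atanh(r).
3. **Weighted degree.** WD(v) = Σ_u z(v,u) over retained links — a voxel's
   total connection strength to the rest of the brain.
4. **Segregation/integration.** Given a parcellation of voxels into
   functional communities, each link is *segregated* (both endpoints in one
   community) or *integrated* (endpoints in different communities); summing
   the two link classes separately gives two maps with
   WD_seg + WD_int = WD_total exactly.
5. **Inference.** Per-voxel OLS GLMs across subjects (group difference, or
   vividness slope within a group) on per-subject standardized maps;
   residual maps give a spatial-smoothness (FWHM) estimate; Gaussian random
   fields smoothed to that FWHM build a null distribution of maximal
   suprathreshold cluster sizes; observed t-maps are thresholded voxelwise
   (two-tailed) and only clusters larger than the null-derived extent
   threshold survive (family-wise α = 0.05).

The behavioral module scores a four-item distal-simulation vividness scale
(1–100, item 4 reverse-scored as 101 − x) and computes pooled two-sample
t-tests from raw scores or from printed summary statistics.

## Worked example

```python
import numpy as np
from wdhub import (SimConfig, PipelineConfig, analyze_cohort,
                   dice_coefficient, group_compare_summary)

# a cohort of 10 + 10 subjects with a planted between-network
# coupling reduction (0.20 -> 0.05) in community 1 of group A
analysis, truth, behavioral = analyze_cohort(
    SimConfig(seed=42), n_per_group=10, config=PipelineConfig(),
    n_iter=1000)

for flavor in ("total", "segregated", "integrated"):
    res = analysis.results[flavor]
    best = max((dice_coefficient(c.voxel_indices, truth.true_effect_voxels)
                for c in res.clusters), default=0.0)
    print(f"{flavor:>10s}: {len(res.clusters)} surviving cluster(s), "
          f"extent threshold {res.null.threshold_size} voxels, "
          f"best Dice vs truth {best:.2f}")

rep = group_compare_summary(36.08, 9.85, 27, 33.73, 7.32, 26)
print(f"group age difference: t({rep.df}) = {rep.t:.2f}, p = {rep.p:.2f}")
```

Output:

```
     total: 5 surviving cluster(s), extent threshold 3 voxels, best Dice vs truth 0.95
segregated: 0 surviving cluster(s), extent threshold 3 voxels, best Dice vs truth 0.00
integrated: 12 surviving cluster(s), extent threshold 3 voxels, best Dice vs truth 0.93
group age difference: t(51) = 0.98, p = 0.33
```

Reading this: the group contrast on total-WD maps recovers the planted
community almost exactly (Dice 0.95 against the planted voxels; group A
shows *lower* hubness there), and the decomposition attributes the effect to
integrated (between-network) links — segregated maps show nothing, as
planted. At the strict voxel-forming threshold the null extent threshold is
small, so a few 3–5-voxel satellites survive next to the dominant effect
cluster; the largest cluster carries the effect. The behavioral helper
reproduces a textbook pooled t from summary statistics alone.

A command-line interface mirrors the library:

```bash
wdhub simulate --config sim.yaml --n-per-group 10 --out cohort/
wdhub preprocess --bold cohort/sub-A01_bold.nii.gz --mask cohort/mask.nii.gz \
    --motion cohort/sub-A01_motion.tsv --nuisance cohort/sub-A01_nuisance.tsv \
    --out clean.nii.gz
wdhub connect --bold clean.nii.gz --mask cohort/mask.nii.gz --q 0.005 \
    --out wd.nii.gz --graph g.h5
wdhub decompose --graph g.h5 --labels cohort/labels.nii.gz \
    --mask cohort/mask.nii.gz --out-prefix sub-A01_
wdhub run --out run1/        # simulate -> ... -> corrected cluster tables
```

## Layout

- `src/wdhub/synthgen.py` — synthetic cohorts with planted effects
- `src/wdhub/preprocess.py` — FD, confound regression, scrubbing, filter, kernel
- `src/wdhub/connectivity.py` — correlation, FDR thresholding, WD maps
- `src/wdhub/netlabels.py` — segregated/integrated decomposition
- `src/wdhub/inference.py` — GLM, smoothness, cluster null, correction
- `src/wdhub/behavior.py` — vividness composite and group statistics
- `src/wdhub/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, formats

See `docs/methods.md` for the model, parameter choices, and limitations.
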