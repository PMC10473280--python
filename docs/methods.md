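# Methods

This note documents the models, parameter choices, and numerical decisions
behind `wdhub`, and what the synthetic validation does and does not show.

## Subject-level connectivity and weighted degree

For a masked voxel×time matrix the package computes all pairwise Pearson
correlations blockwise (peak memory O(block × voxels); the dense
voxel×voxel matrix is never materialized). Link significance uses the
parametric one-sided (positive-tail) p-value from
t = r·√((n−2)/(1−r²)) with n the number of frames. One-sided is the
default because negative correlations are discarded anyway (their
interpretation after nuisance regression without global signal regression
is contested); a two-sided mode exists. Interpolated (scrubbed) frames are
counted in n by default; a censored-dof alternative is available through
the `n_effective` argument.

Benjamini–Hochberg FDR at q < 0.005 is applied **jointly across all
upper-triangle in-mask links** of a subject, giving a single coherent null
per subject. Because the one-sided p is strictly decreasing in r, the
step-up cutoff is evaluated in r-space by the downward fixed-point
iteration k → #{p ≤ k·q/m}; this is algebraically identical to the textbook
step-up on the full p-vector (a property the test suite checks against a
brute-force oracle) and avoids materializing millions of p-values.
Surviving links are weighted by Fisher's z = atanh(r), clipped at
|r| = 1 − 1e-7 with a warning; weighted degree is the sparse row sum.
Zero-variance voxels are excluded from the graph (WD 0, logged count).

Segregated/integrated decomposition partitions retained links by endpoint
community equality. Per-voxel sums over the two classes reconstruct total
WD exactly up to float summation order (≤ 1e-12 in tests).

## Preprocessing

Stage order defaults to regress → scrub/interpolate → band-pass → smooth;
interpolating motion spikes before filtering avoids spectral leakage from
step discontinuities. The order is an explicit argument.

* **Confound model:** intercept, 6 rigid motion parameters and their
  backward differences (frame 0 difference defined 0), linear and quadratic
  trends, and 5+5 anatomical component regressors read from a table. Global
  signal is deliberately not a regressor. Rank deficiency raises an error
  naming the collinear columns.
* **Framewise displacement (Jenkinson):** RMS displacement of a solid
  80-mm-radius sphere under the relative rigid transform between
  consecutive frames, √(R²/5·tr(AᵀA) + |b|²); frames with FD > 0.2 mm are
  flagged and linearly interpolated from the nearest clean frames (nearest
  value at the ends). Rotations compose as Rz·Ry·Rx; at head-motion angles
  the composition order is numerically irrelevant (checked against a
  Monte-Carlo sphere-integration oracle at 2%).
* **Band-pass:** zero-phase forward–backward Butterworth of order 4,
  0.01–0.08 Hz. Pass-band sinusoids retain ≥ 99% amplitude, a 0.20 Hz
  probe retains < 0.1%.
* **Smoothing:** masked normalized convolution with an isotropic Gaussian,
  σ = FWHM/(2√(2 ln 2)) converted to voxel units per axis; out-of-mask
  voxels contribute no kernel mass, so constants are preserved inside the
  mask.

## Group inference

Per-voxel OLS with an explicit design matrix; the two-group design
reproduces the pooled two-sample t exactly. **Each subject's WD map is
standardized (z-scored across in-mask voxels) before group modeling**
(a flag disables this). The joint FDR cutoff makes a subject's retained
link density a global scalar mode of its WD maps; without standardization
a chance group imbalance in that scalar shifts every voxel together and
produces diffuse, whole-mask "differences" that cluster-extent correction
cannot calibrate. Standardizing degree maps before group statistics is the
common practice in the voxel-wise centrality literature; the contrasts then
test the spatial pattern of hubness rather than overall link density.

Spatial smoothness of the residual maps is estimated per axis with the
variance-of-spatial-derivatives estimator: ρ̂ = 1 − var(Δ)/2·var over
in-mask neighbor pairs pooled across maps, FWHM = d·√(−2 ln 2 / ln ρ̂)
(d = voxel size) — the width of the Gaussian kernel that would give white
noise that lag-one autocorrelation. ρ̂ is clipped to (1e-8, 1−1e-8);
constant residuals are an error.

The cluster null follows the classic Monte-Carlo approach: Gaussian white
noise on the grid, smoothed to the estimated per-axis FWHM, standardized
in-mask, thresholded two-tailed at the voxel-forming p pooling tails by
absolute value, largest suprathreshold component recorded
(26-connectivity default; 6/18 available). The extent threshold is the
smallest integer k with P(max ≥ k) ≤ 0.05 in the null sample, so keeping
clusters of ≥ k voxels controls family-wise error at 0.05 (slightly
conservatively, given integer sizes). The default iteration count is
10,000; tests and the acceptance script use 1,000 for speed.

**Voxel-forming threshold.** The default is a strict two-tailed p = 0.005
(the cluster-level α stays 0.05; both knobs are exposed). At liberal
primary thresholds (p ≈ 0.05), extent correction against Gaussian-matched
nulls is known to be anticonservative: real t-maps contain diffuse,
low-amplitude correlated fields whose suprathreshold components are larger
than the matched-FWHM Gaussian null predicts. In our validation cohorts
the no-effect false-survivor rate at p = 0.05 was several times the nominal
5% and fell to the nominal level at p = 0.005, with no loss of true-effect
detection.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis consumes,
not scanner physics. Each voxel in community c is

    x_i(t) = √a_c·L_c(t) + √b_c·G(t) + noise_sd·e_i(t) + 1000

with loadings solved analytically so the within-community correlation is
`within_r` (default 0.5) and the between-community correlation `between_r`
(default 0.2): v = noise_sd²/(1−within_r), b_c = between_r·v,
a_c = (within_r−between_r)·v. For group-A subjects the effect community's
global loading is re-solved so its cross-community correlation equals
between_r − δ (subject-level δ jittered around `effect_delta`, default
0.15) while its within-community correlation is unchanged — the planted
effect is purely between-network.

* **Latents** (one per community plus one global) are band-limited to the
  canonical resting-state fluctuation band 0.01–0.08 Hz and
  sample-orthonormalized (QR), so the realized coupling equals its targets
  exactly rather than in expectation. Broadband latents would lose ~80% of
  their variance to the band-pass stage, leaving ~84 effective degrees of
  freedom; their sample cross-correlations would then fluctuate coherently
  per subject, adding community-block noise to WD maps under the null that
  a Gaussian-FWHM cluster null cannot calibrate. Slow, band-limited network
  fluctuations are also the physiologically sensible model.
* **Voxel noise** is broadband — an AR(1) (coefficient 0.3) plus white
  mixture — so the band-pass stage operates on a non-flat spectrum and
  supplies the independent per-voxel sampling variability that makes
  between-subject WD noise short-range.
* **Geometry:** 12×12×12 grid of 6-mm voxels (72-mm field of view), K = 5
  compact contiguous blocks from recursive bisection. Voxel size and block
  shape keep the 6-mm smoothing kernel (≈ 1 voxel FWHM) small relative to
  community extent, mirroring the full-scale setting where functional
  networks are orders of magnitude larger than the kernel. With thin
  communities the kernel mixes time series across community borders and a
  purely between-network effect would bleed into segregated maps.
* **Subject heterogeneity:** optional spreads on per-subject within/between
  coupling (`within_r_subject_sd`, `between_r_subject_sd`) default to 0.
  Nonzero values create global coupling differences between random groups
  that are real group differences — useful for robustness studies, but they
  violate the exchangeable-null premise of the planted-effect validation.
* **Motion:** slow random-walk drift plus one-frame translation spikes
  (probability `motion_spike_prob` per frame, 0.3–0.8 mm) that exceed the
  0.2-mm FD threshold and exercise scrubbing. **Nuisance tables:** ten
  unit-variance component series. **Behavior:** four vividness items on the
  1–100 scale around a composite 60 + slope·(100·δ) with item noise; item 4
  is stored inverted (difficulty) so reverse-scoring is exercised;
  `behavioral_slope` defaults to −1 composite point per percentage point of
  coupling reduction.
* Everything is a pure function of integer seeds; identical configuration
  and seeds give bit-identical outputs.

### What passing the synthetic validation does and does not show

The generator's compound-symmetric community model, exact latent
orthogonality, and homogeneous cohorts are idealizations. Passing shows the
pipeline is internally correct (oracle-exact kernels, conserved
decomposition, calibrated extent null under matched smoothness) and can
detect and localize a between-network coupling reduction of 0.15 at
n = 10+10 and 400 frames while leaving segregated maps quiet. It does not
show robustness to global coupling heterogeneity, non-stationary
autocorrelation, distance-dependent motion artifacts, or physiological
confounds of real BOLD — on real data the strictness of the voxel-forming
threshold and the map standardization matter even more, and permutation
inference would be the more robust (but heavier) choice.

## Defaults

| Parameter | Default | Notes |
|---|---|---|
| FDR level q | 0.005 | joint across all links, per subject |
| FD threshold / radius | 0.2 mm / 80 mm | Jenkinson RMS convention |
| Band-pass | 0.01–0.08 Hz | order-4 Butterworth, zero phase |
| Smoothing FWHM | 6 mm | masked normalized convolution |
| Null iterations | 10,000 | 1,000 in tests/acceptance for speed |
| Voxel-forming p | 0.005 two-tailed | see rationale above |
| Cluster α | 0.05 | smallest k with P(max ≥ k) ≤ α |
| Connectivity | 26 | 6/18 available |

Problem sizes used in the validation suite — 12³-voxel grids, 10+10
subjects, 400 frames, 25 seeds, 1,000-iteration nulls — are the package's
desk-scale study conditions; the implementation streams correlations in
blocks so substantially larger masks are feasible.

## Known limitations

* The smoothness estimator assumes a Gaussian-shaped autocorrelation;
  heavy-tailed ACFs (as in real fMRI) are under-modeled, which is the
  standard failure mode of matched-FWHM cluster simulation.
* The null simulates Gaussian fields, while observed maps are t-fields with
  few degrees of freedom; at strict voxel thresholds the discrepancy is
  small but it is the reason the strict default exists.
* aCompCor components are consumed as a provided table; extracting them
  from tissue masks is upstream of this package.
* No surface-based analysis, no alternative centrality measures, no
  permutation-based FWE.
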