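# Methods

This note documents the models, numerical conventions and design choices
behind `hubcausal`, and what the synthetic validation does and does not
demonstrate.

## The inferential chain

The pipeline reproduces, stage by stage, the standard resting-state
network-architecture protocol for a two-group clinical comparison:

1. **Preprocessing** (per subject): discard the first 10 volumes (signal
   equilibration), spatial smoothing (Gaussian, FWHM 6 mm), per-voxel
   linear detrend, ideal band-pass 0.01–0.08 Hz. Smoothing precedes the
   temporal operations, matching the protocol's listed order. Registration
   steps (slice timing, realignment, normalisation) are out of scope:
   inputs are already on a common 3 mm template grid. Subjects whose
   realignment parameters exceed 2.0 mm translation or 2.0° rotation on
   any axis (strict inequality) are excluded before analysis.
2. **Degree centrality** (per subject): Pearson correlation of every
   gray-matter voxel (tissue probability > 20 %, strict) with every other;
   edges at r > 0.25, strict, positive only; weighted (default) or
   binarized degree; z-standardisation with the population SD, so every
   map has in-mask mean 0 and SD 1 exactly. Zero-variance voxels stay in
   the mask with degree 0.
3. **Cluster-extent correction**: Monte-Carlo simulation of in-mask
   Gaussian noise smoothed to FWHM 6 mm (masked smoothing renormalised by
   the smoothed mask, avoiding edge attenuation), re-standardised,
   thresholded at the one-tailed upper voxel-p normal quantile; the
   minimum cluster size is the smallest extent with null exceedance
   probability ≤ the corrected alpha. Connectivity is geometric (center
   distance ≤ 5 mm ⇒ 18-connectivity at 3 mm voxels). Two-sided map
   inference runs the two tails separately at voxel-p each.
4. **Group inference**: per-group one-sample t maps (df n−1) are
   corrected and their surviving positive clusters unioned into the
   analysis mask for the two-sample stage; the group contrast is a
   voxel-wise GLM with intercept, +1/−1 group coding and mean-centered
   age, sex (male = 1) and education; t on the group column with
   df = n − rank. Constant covariate columns are dropped, which reduces
   the model to the classic pooled two-sample t-test.
5. **Seed Granger causality** (per subject, per seed): seed spheres of
   radius 6 mm at (±18, 42, 27); bivariate order-1 autoregressions give
   F_x→y and F_y→x per voxel with
   F = [(RSS_r − RSS_f)/p] / [RSS_f/(T − 2p − 1)]; each direction's F map
   is z-standardised over the mask. Seed-sphere voxels are excluded from
   the group-level Granger mask (no self-prediction). The model order
   p = 1 is the package default and configurable.
6. **Clinical correlations**: mean z values of surviving clusters,
   patients only, against THQ and tinnitus duration; partial Pearson
   correlation (residualising both variables on intercept + age + sex +
   education), p from t = r·√((n−k−2)/(1−r²)) two-tailed, Bonferroni
   factor = clusters × clinical variables, reported explicitly.
7. **Demographics table**: continuous variables by pooled-variance
   two-sample t (computable from printed group summaries alone);
   sex by Pearson chi-square without continuity correction. These two
   conventions are what reproduce the published cohort-table p-values
   (age p = 0.145, sex p = 0.813) from the printed summaries.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `r_threshold` | 0.25 | correlation edge threshold (strict >) |
| `gm_prob_threshold` | 0.20 | gray-matter inclusion (strict >) |
| `voxel_p` | 0.01 | per-voxel significance before cluster correction |
| `corrected_alpha` | 0.01 | family-wise cluster-level alpha |
| `n_mc_sims` | 5000 | Monte-Carlo null simulations |
| `fwhm_mm` | 6.0 | smoothing kernel and assumed null smoothness |
| `connect_radius_mm` | 5.0 | cluster connection radius |
| `band` | 0.01–0.08 Hz | retained fluctuation band |
| `discard_volumes` | 10 | equilibration frames dropped |
| `motion_limit_mm/deg` | 2.0 / 2.0 | exclusion limits (strict >) |
| `gc_order` | 1 | autoregression order |
| `seed_radius_mm` | 6.0 | seed sphere radius |
| `dc_flavor` | weighted | degree definition used at group level |

## The synthetic cohort

No scan data are distributed with the protocol, so validation runs on a
generator that emulates the study conditions: 24 patients + 22 controls,
TR 2 s, 240 volumes, a 20×24×20 grid of 3 mm voxels with origin
(−27, −18, −21) — placed so both 9 mm hub spheres at (±18, 42, 27) lie
fully inside — and a deterministic gray-matter phantom (separable edge
taper) whose > 0.2 mask holds 7120 voxels.

Per subject, BOLD = (a) spatially white AR(1) noise (coefficient 0.3),
variance-scaled so that preprocessing's 6 mm smoothing leaves it at unit
variance and *exactly* the smoothness the cluster-level null assumes;
(b) four band-limited (0.01–0.08 Hz) network time courses, orthonormalised
over the post-discard window, mixed into gray matter through smooth
(9 mm) cohort-level random loading fields (SD 0.15); (c) a small random
linear drift. Demographics are truncated-normal draws matching the
published group summaries; one optional extra patient exceeds the motion
limits to exercise the exclusion path.

Patient-only injected effects (`EffectSpec`):

* **Hub**: a shared band-limited signal added at gain 0.9 inside the two
  hub spheres and at 2 % of that gain across gray matter. Sphere voxels
  become strongly intercorrelated, raising their suprathreshold degree.
* **Directed coupling**: each target sphere (radius 6 mm, centers
  (±12, 0, 0)) receives strength × the source-sphere mean delayed by one
  volume; per-patient strengths ~N(0.6, 0.2²) clipped ≥ 0.1. The source is
  untouched, so the induced influence is purely directional.
* **THQ**: patient scores are constructed with an exact-correlation
  device (target r = 0.5 with the coupling strengths before clipping to
  [0, 100]), mean 49.5, SD 15.5.

### Why the generator looks the way it does

Three choices exist specifically so that the *null* chain is calibrated —
with all effects zero, the corrected two-sample map should be clean in
≥ 95 % of cohorts:

* The noise leaves the generator spatially white. Noise smoothed at
  generation *and* in preprocessing would be ~8.5 mm smooth while the
  Monte-Carlo null assumes 6 mm, making cluster correction
  anti-conservative.
* Network time courses are orthonormalised per subject. Finite-sample
  correlations between network signals otherwise induce long-range,
  loading-shaped fluctuations in each subject's degree map — structure
  that no fixed-smoothness cluster null can absorb.
* Network engagement is identical across subjects (amplitude jitter 0).
  Between-subject amplitude variability creates coherent network-shaped
  null t-map structure for the same reason.

The baseline graph is deliberately sparse (~1–3 % of voxel pairs above
r = 0.25). A dense baseline leaves a large mass of near-threshold edges,
and then any injected variance change redistributes huge numbers of edges:
per-subject z-standardisation turns that into broad secondary clusters
that can exceed the hub itself. At the sparse operating point the hub's
own within-/cross-sphere edges dominate and the z-renormalisation artifact
(a genuine, known property of relative degree measures — adding degree
somewhere must lower z elsewhere) stays well below cluster threshold.
Hub gain 0.9 and coupling strength 0.6 are the calibrated detectability
point for n = 24 + 22: strong enough that recovery succeeds in ≥ 8 of 10
seeds, weak enough that the artifact does not overtake the hub and the
coupling target does not become the dominant degree cluster.

### What the synthetic validation does not show

The generator omits physiological noise (cardiac/respiratory),
scanner drift beyond a linear trend, subject-specific anatomy and
registration error, hemodynamic-response variability (the Granger analysis
runs on BOLD directly — directional estimates on real data can be
confounded by regional hemodynamic latency differences), hearing-loss
structure, and any true coupling between demographics and connectivity.
Passing recovery tests therefore demonstrates the *inferential chain* is
correct and calibrated under its own assumptions, not that those
assumptions hold in scanner data. The published cohort's specific peak
coordinates, t values and correlation coefficients are properties of
undeposited raw scans and are not reproduced quantitatively; the output
formats (cluster tables with peak MNI/stat/extent, correlation reports
with r, raw and Bonferroni p) mirror the published tables so real data
would be reported identically.

## Numerical conventions

* Voxel indices are 0-based; the affine follows the NIfTI sform; reported
  peaks are MNI mm. Grids must match across subjects within 1e-4 mm; no
  resampling.
* The band-pass is an ideal (rectangular) DFT filter, bins
  low ≤ f ≤ high inclusive; the DC bin is removed whenever low > 0.
* Smoothing uses zero padding; edge voxels are attenuated (documented
  because it affects them), except in the Monte-Carlo null where masked
  smoothing renormalises by the smoothed mask.
* Degree uses the population (divide-by-N) SD in Eq. Z = (D − D̄)/σ_D: the
  map is standardised as a fixed object, not a sample estimate; σ_D = 0
  yields an all-zero z map with a warning.
* Blocked and full degree computation agree to 1e-10; the pipeline runs
  the blocked route in float32 (agreement with float64 ~1e-7, far below
  any decision threshold).
* The Granger F uses the protocol's stated denominator df (T − 2p − 1
  with T the series length); empirically the null rejection rate at the
  F(1, T−3) 5 % quantile is 0.049 (8000 draws). Exactly collinear series
  produce a large finite F (tiny-RSS guard); constant series are flagged
  and set to F = 0. The batched per-voxel solver adds a 1e-12 ridge to the
  Gram matrices and agrees with the looped two-regression route to ~1e-8.
* Cluster labeling uses a 3×3×3 structuring element when the connection
  radius allows (the 5 mm/3 mm case), else a general sparse
  connected-components route; both match a brute-force union-find oracle.
* Ties: all thresholds in the chain are strict inequalities (r > 0.25,
  probability > 0.2, motion > 2.0, stat > t_crit), matching the protocol's
  wording; boundary values are tested explicitly.

## Problem sizes used in validation

Unit tests run on toy grids (≤ 10³ voxels) against brute-force oracles.
The acceptance-level suite runs: degree oracle equivalence on 20 random
instances up to 200 voxels × 230 frames; Monte-Carlo calibration at 1000
simulations on a 4096-voxel mask with 500 fresh null maps; Granger null
calibration at 1000 replicates of T = 230; and end-to-end recovery on ten
24 + 22-subject cohorts at the full 20×24×20 grid with 230 retained
volumes and 1000-simulation corrections. The null-calibration run uses
twenty study-scale cohorts with zero injected effects. These sizes are the
package's chosen validation scale; the protocol value n_mc_sims = 5000
remains the library default.

## Known limitations

* Cluster-extent correction assumes the statistic map's noise smoothness
  equals the stated FWHM; the package imposes rather than estimates it.
  On real data with heavier spatial autocorrelation the correction is
  anti-conservative (the same caveat applies to the original protocol).
* Bivariate (not conditional) Granger causality: influence through a
  third region is not partialled out, and no hemodynamic deconvolution is
  applied.
* The z-scored F maps inherit the F distribution's right skew; the
  z-transform equalises location and scale across subjects, not shape.
* Partial correlation is the only "corrected for age, sex, education"
  interpretation implemented for the clinical analysis; plain Pearson is
  available as a routine.
* No resampling, registration, atlas labeling or surface support.
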