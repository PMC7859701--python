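# Methods

`tzpheno` quantifies fluorescence phenotypes of the ciliary transition
zone (TZ) in *C. elegans* phasmid neurons, scores three cilia-dependent
behavioural assays, and applies a normality-gated multi-group comparison
to any resulting metric table.  Because no raw microscope data
accompany the measurement conventions it implements, every estimator is
validated by **parameter recovery**: a synthetic-scene generator renders
images with known ground truth, and the test suite demands that the
estimators recover that truth within stated tolerances.

## Measurement model

### Wide-field 2D metrics (`tz_quant`)

- **Line profiles.** Profiles are sampled along a user-drawn polyline at
  one-pixel arc steps by bilinear interpolation, averaged over a
  configurable perpendicular width (default 1 px, the ImageJ default; the
  original workflow's line width is unrecorded).  At the wide-field
  calibration of 0.08 µm/px, a 20-pixel scan spans 1.6 µm.  The first
  polyline anchor is the proximal (ciliary-base) end everywhere.
- **FWHM signal length.** The half-max level is
  `baseline + (max − baseline)/2` with the baseline defaulting to the
  profile minimum (profiles are drawn on raw images, without a separate
  background step for the length metric).  The length is the distance
  between the *outermost* half-max crossings flanking the global maximum,
  linearly interpolated between samples.  Taking the outermost crossings
  makes the metric robust to periodic axial modulation that dips below
  half max inside the signal.  A profile that starts or ends above the
  half-max level is reported as truncated rather than silently clipped.
- **Integrated box intensity.** The TZ pair's integrated intensity in an
  inner box (default 40×40 px) is corrected by the per-pixel background
  estimated from the one-pixel ring between the inner box and a box
  enlarged by one pixel per side (42×42; ring of 164 px).  Because the
  ring is centre-symmetric about the box, the estimator is exactly
  unbiased under constant and linear background fields — a property the
  tests verify by construction.  Negative net intensities are retained so
  group means stay unbiased.  The box is placed on a user-annotated
  centre (the centroid of the TZ pair); the pair is measured jointly.
- **Normalisation and competition index.** Group values are divided by
  the reference (wild-type) group mean (a median option exists; which
  centre the original convention used is unstated).  The allele
  competition index is `100 × mean(het) / mean(homo)`, so the homozygous
  reference maps to 100% by construction and equal allele recruitment
  predicts 50%.
- **Axial distribution averaging.** Profiles are aligned at their
  proximal half-max crossing before pointwise averaging (mean ± s.d.).
  The alignment rule is a design choice — no convention is recorded for
  the original averaging — and is chosen because it preserves
  proximal-peak signatures in the group mean.  When a reference group is
  supplied the mean profile is divided by the reference group's peak
  mean.
- **Asymmetry index.** Our quantification of "proximally enriched": the
  fraction of background-subtracted signal in the proximal half of the
  signal window; 0.5 is symmetric, larger is proximally enriched.  The
  window is the contiguous above-baseline support around the global
  maximum (default) rather than the FWHM window: for a right-triangle
  profile the support window yields the closed-form value 3/4, whereas
  an FWHM window would split the triangle at its half-max crossing and
  yield 7/12, conflating peak sharpness with asymmetry.  A `window="fwhm"`
  option is provided.
- **Leakage along a cilium.** Periciliary-protein signal is read from a
  profile along the cilium trace (drawn base → beyond tip).  Background
  is the mean over the final stretch of the trace beyond the ciliary tip
  (default 1 µm).  Two read-out conventions: a point read-out at 4 µm
  from the base (RPI-2), or the mean over 2–4 µm (TRAM-1).
- Trace length is the polyline path length × pixel size; the basal-body
  span is the extent of the annotated points projected on the anatomical
  axis; maximum projection is the per-pixel max over z.

### Super-resolution 3D metrics (`volumetrics`)

Stacks are resampled in z from the acquisition step (0.2 µm) to a 0.1 µm
modelling step by linear interpolation before segmentation.  The
compartment mask keeps voxels above `background + 0.5 × (max −
background)`; background is the mode of the intensity histogram (robust
for mostly-empty stacks), and the mask is restricted to the largest
26-connected component (26-connectivity keeps thin shells connected).
The 0.5 threshold is configurable and recorded in the output, since the
original surface-rendering settings are unpublished; absolute volumes
are therefore meaningful only relative to one another, and the tests
assert ordinal behaviour plus agreement with a dense-grid optical oracle
(below), not agreement with any published absolute volume.

- **Axial peak count.** Local maxima of the axial intensity profile with
  topographic prominence ≥ 20% of the profile's dynamic range.  The
  profile sums background-subtracted intensity per axial position over a
  more permissive support mask (threshold fraction 0.1) than the volume
  mask: at the 0.5 volume threshold the troughs of a periodic shell fall
  below threshold and would disconnect the component, truncating the
  profile to a single crest.  The 20% prominence separates the 3–4-peak
  pattern from noise at the simulated SNR.
- **Hollowness.** Core-to-shell intensity ratio, assessed in the z plane
  nearest the compartment's intensity-weighted z centroid — the
  "central plane" convention used when judging hollow cores by eye.  The
  in-plane radial profile about the axis polyline is binned at pixel
  resolution; the shell radius estimate is the radius of peak intensity;
  the ratio is the mean over core bins (≤ 1/3 shell radius) divided by
  the peak-bin mean.  Values < 1 indicate a hollow core, ~1 a solid
  compartment.  With 0.2 µm z steps a stack whose best plane misses the
  axis under-reports hollowness — the same limitation the acquisition
  itself has ("hollow core not always observed in the central plane").
  A flat radial profile (no structure above background) raises rather
  than returning a meaningless ratio.

### Behavioural assays (`behavior`)

Dye filling: per-genotype frequency of worms with 0–4 dye-filled phasmid
neurons, trials pooled.  Roaming: per-worm grid-square counts divided by
the reference genotype's mean.  Osmotic avoidance: fraction of worms
remaining in the ring at each time point on a 1-min grid, right-censored
at 10 min; censored worms never escape; the final (10-min) retention is
the value passed to group comparisons.  Worms missing a field are
excluded per-assay, not per-cohort.

### Group statistics (`group_stats`)

A Shapiro–Wilk test per group (α = 0.05) gates between one-way ANOVA
with Tukey's HSD (all groups pass) and Kruskal–Wallis with Dunn's post
hoc (otherwise); the gate verdict is recorded, and a forced override is
honoured and flagged.  The decision rule "all groups pass ⇒ parametric"
is our choice; only the gate's purpose is documented in the convention
we follow.  Tukey uses the Tukey–Kramer form for unequal n (via
`scipy.stats.tukey_hsd`; cross-checked against statsmodels in the
tests).  Dunn's test uses tie-corrected rank z statistics with
Bonferroni adjustment over all pairs — the correction used by the
original spreadsheet add-in is unknown, so the choice is recorded in the
output and exact reproduction of published p-values is not attempted.
The suite calibrates the full gated pipeline's type-I error on a
2000-replicate 4-group null simulation (accepted band 3–7% at α = 0.05).

## Synthetic scenes (`synthetic`)

The generator renders what the pipeline is meant to measure:

- **Geometry.** Each cilium runs along x: a TZ (default length 0.8 µm)
  modelled as a hollow cylindrical shell (radius 0.125 µm, thickness
  0.05 µm), followed by ~3 µm middle and ~3 µm distal segments carried
  on a solid pan-ciliary "marker" channel (radius 0.1 µm), with an
  optional "leakage" channel uniform along the cilium.  Wide-field
  scenes contain a phasmid pair (1 µm apart); super-res scenes a single
  TZ.  The shell radius is below wide-field resolution but resolvable at
  super-res, so the hollow core is a super-res-only feature, as
  observed.  No radius or brightness is documented for the real
  structures; all values are configurable.
- **Axial structure.** Shell intensity is modulated as
  `1 − m·cos(2πPx/L)` with depth m = 0.5, giving exactly P interior
  maxima (the ground truth for peak-count recovery); an optional
  exponential proximal→distal decay (scale `asymmetry_decay_um`) creates
  proximal enrichment.  The phase is chosen so the modulation contributes
  no end-spikes and the recoverable count equals P.
- **Optics.** Emitters are laid on a fine grid (2× supersampled xy for
  wide-field; native xy and z_step/4 for super-res), convolved with a
  separable Gaussian PSF truncated at 4σ and renormalised (wide-field
  FWHM 0.25 µm — typical for a 1.4-NA objective at ~510 nm; super-res
  FWHM 0.1486 µm).  Super-res stacks default to an isotropic PSF: they
  emulate the deconvolved output that 3D modelling consumes; a
  `psf_axial_factor` models raw axially-elongated confocal data instead.
  Wide-field images are z-projections of the blurred field (so photon
  mass is conserved exactly); super-res stacks *sample* the blurred
  field at discrete planes 0.2 µm apart, as a confocal z-stack does —
  consequently stack totals are only proportional to emitted photons
  unless the step matches the render grid, and the scene geometry places
  the cilium axis on an acquisition plane so that the central slice cuts
  the shell axis.
- **Noise.** Poisson shot noise on signal + background (a constant level
  plus an optional linear gradient along x, which exercises the ring
  estimator's unbiasedness), then Gaussian read noise, clipped at zero.
  Default amplitudes put peak-pixel SNR near 20 (wide-field) and 15
  (super-res), comfortably above the SNR ≥ 10 regime the recovery
  properties are stated for.
- **Determinism.** All randomness flows from
  `numpy.random.default_rng(seed)`; identical parameters give
  bit-identical scenes and cohorts.

Preset conditions: `widefield`/`superres` (wild-type-like: uniform or
3-peak shell) and `widefield_g155s`/`superres_g155s` (disrupted-variant-
like: amplitude ×0.25, two axial peaks, proximal decay 1.2 µm).  The
decay scale is the smallest that leaves the distal second peak clearly
prominent after PSF blur and thresholding — the emulated phenotype shows
both proximal enrichment *and* two discernible peaks, so a faster decay
would contradict the condition being modelled.

**Competition model.** Heterozygote fluorescence is modelled as two gene
products competing for a saturable pool of TZ docking sites: the tagged
(visible) share is `k_tagged / (k_tagged + k_untagged)` of the
homozygote capacity — one half under equal recruitment, approaching 1
when the untagged competitor cannot be incorporated.  Cohorts add
multiplicative lognormal scatter of stated CV (unit mean).

**Behavioural cohorts.** Dye counts are drawn from a 5-category
distribution; roaming counts are negative-binomial (mean, dispersion) to
allow the overdispersion behavioural counts show; escape times are
exponential with the stated hazard, right-censored at 10 min.

## What the simulations do and do not show

The generator reproduces the *statistical structure* of the assays
(signal geometry, photon noise, background gradients, censoring,
overdispersion) but not autofluorescent debris, neighbouring-cell
signal, focus drift, annotation error, or deconvolution artifacts.
Passing recovery tests therefore demonstrates that the estimators are
correct and calibrated for data of the stated structure — not that any
particular biological effect size in real images is reproduced.
Published effect sizes from real micrographs (which are not deposited)
are out of reach at desk scale; the end-to-end check instead verifies
the qualitative disruption signature: lower net intensity, shorter
FWHM, proximal asymmetry > 0.5, fewer axial peaks, reduced volume.

## Numerical choices and problem sizes

- FWHM/crossing interpolation is linear between samples; box placement
  rounds the annotated centre to the nearest pixel.
- Compartment volume is voxel count × (pixel² × z step); the volume
  oracle in the tests is a dense-grid (2 nm / 1 nm) computation of the
  blurred shell's half-max volume including z sampling, independent of
  the voxel pipeline.  A bare geometric shell volume (2πR·t·L) is *not*
  the quantity a half-max threshold of PSF-blurred data measures — it is
  smaller by roughly the ratio of blurred to true shell thickness.
- Test problem sizes: 50 wide-field scenes for recovery medians, 100
  super-res stacks per condition for peak counts, 30 for hollowness,
  2000 replicates for the type-I calibration, 20 end-to-end replicates
  of 12 scenes per genotype; chosen to hold Monte-Carlo error well below
  each acceptance band on a single CPU.
- Seeds are fixed constants in the tests; the acceptance script derives
  all seeds from its `--seed` argument.

## Known limitations

- No automated TZ detection; annotations are inputs, mirroring a manual
  workflow.  No deconvolution, flat-field, or chromatic correction.
- Absolute compartment volumes depend on the (unpublished) thresholding
  convention; only relative comparisons are supported.
- Hollowness from 0.2 µm z stacks depends on sampling phase; stacks
  whose planes miss the shell axis under-report the hollow core.
- The Dunn correction (Bonferroni) is deliberately conservative; other
  corrections will give smaller adjusted p-values.
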