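# Methods

This note documents the models, estimators and numerical choices behind
`condenskit`, and what the synthetic-data generators do and do not emulate.

## Displacement-CDF diffusion analysis

Single-molecule tracks of a membrane-associated kinase confined to a polar
microdomain are short (tens of frames at 20-ms integration) and slow
(D ~ 10⁻³–10⁻¹ μm²/s), so per-track MSD fits are hopeless. Instead all
squared displacements at a fixed lag are pooled and their empirical CDF is
fit. For isotropic Brownian motion in *d* dimensions with per-axis
localization error σ, the squared displacement over lag Δt is distributed as
s²·χ²_d with per-axis variance s² = 2DΔt + 2σ², giving the mixture model

    F(u) = Σ_j α_j · P(d/2, u / (2 s_j²)),    s_j² = 2 D_j Δt + 2σ²,

where P is the regularized lower incomplete gamma function; for d = 2 this
is the familiar 1 − exp(−u / (4DΔt + 4σ²)). Parameters are estimated by
least squares between model and empirical CDF on the sorted displacement
grid, with diffusivities parameterized in log space and mixture weights via
softmax, multi-started over a log-spaced diffusivity grid anchored at the
median displacement scale. Ties are broken toward the smaller leading
diffusivity for determinism.

Choices and caveats:

* **Overlapping frame pairs** are pooled. This maximizes counts from short
  tracks at the cost of correlated observations; the least-squares (not
  likelihood) objective tolerates the correlation, but the reported
  residuals are not independent and no standard errors are quoted from the
  fit itself.
* **Default dims = 2** (x, y), even for 3D localizations, matching the 2D
  projection convention of the tracking data; `dims=3` is a flag.
* **Localization error** enters only as a variance offset 2σ² per axis
  (σ ≈ 30 nm laterally at the emulated acquisition). σ can be fixed
  (recommended; it is measured upstream) or fit.
* **Polar occupancy** is one vote per trajectory: a track is polar iff the
  per-axis median of its positions lies within the pole radius. The
  operational pole definition (center + radius) must be supplied; nothing in
  the localization table marks the pole.
* `msd_curve` exists as a cross-check: for free 2D diffusion with σ = 0 the
  MSD slope / 4 and the CDF-fit D agree within 10% at n ≈ 2000 tracks
  (tested).

## FRAP quantification

Movies follow the emulated acquisition: 100-ms exposure every 1 s for 100
frames, bleach between the third and fourth captures (so frames 0–2 are
prebleach and frame 3 is the first post-bleach frame, 0-based).

Pipeline: (1) per-frame scalar background, measured as the mean over
condensate-free ROIs, is subtracted from every pixel; (2) three region
traces are extracted — I1 bleached spot, I2 unbleached control condensate,
I3 whole bleached condensate; (3) normalization:

* **literal mode** (default): n(t) = (I1 − I2) / I3, per frame. Division by
  I3 cancels per-frame multiplicative gain (laser fluctuation).
* **divisive mode**: n(t) = I1 / I2. This cancels both gain and acquisition
  photobleaching (the control carries the same fade), and it remains
  well-defined in the degenerate case where the control condensate is as
  bright as the bleached spot was before the bleach — there (I1 − I2) ≈ 0
  prebleach and the literal normalizer blows up. The literal mode detects
  this (|prebleach mean| < ε × prebleach I3 scale, ε = 10⁻⁶ by default,
  configurable) and errors with a pointer to the divisive mode rather than
  emitting an unstable curve.

Finally N(t) = n(t) / mean(n over prebleach frames), so the prebleach level
is 1 and curves are fractional recovery. In divisive mode the plateau of N
equals f_m·d + (1 − d) for bleach depth d and mobile fraction f_m,
independent of the fade rate (tested against the generator).

Replicate averaging aligns curves at the bleach frame and reports pointwise
mean ± SEM (sd/√n). Values at each time point are sorted before reduction so
the result is bit-identical under permutation of the input curves.

The optional recovery fit is the single-exponential reaction-dominant model
N(t) = F0 + (F∞ − F0)(1 − e^{−(t−t_b)/τ}) on post-bleach frames, initialized
from the first post-bleach value, the mean of the last 10% of frames, and
the time to half-plateau, with a ×/÷3 multi-start on τ. The mobile fraction
(F∞ − F0)/(1 − F0) is clamped to [0, 1] with a flag; a flat post-bleach
curve returns f_m = 0 with τ flagged unidentifiable. No reaction–diffusion
PDE modeling, spatial recovery profiles, or bleach-pulse diffusion
correction is attempted.

## Condensate and cell intensity scores

* **Enrichment** E = (mean_in − mean_out)/mean_out per condensate, with
  mean_out taken over *all* non-condensate pixels of the field of view (not
  an annulus). E is invariant under global multiplicative scaling and shifts
  predictably under additive offsets (E → E·b/(b+c) for offset c on
  background b, tested), which is why offset subtraction is mandatory before
  scoring; the code refuses fields whose outside mean is ≤ 0.
* **Localized-to-diffuse ratio** R = (mean_cluster − mean_noncluster)/
  mean_cell per cell, clusters thresholded inside each phase-segmented cell
  (Otsu on the smoothed in-cell intensities by default, fixed level
  optional). Cells with no cluster passing threshold get R = 0 with a flag,
  keeping population distributions well-defined. Cross-channel mode defines
  clusters on one channel and measures intensities on the other.
* **Segmentation** is Gaussian smoothing → threshold (Otsu or fixed) →
  4-connected components → minimum-area filter. 4-connectivity avoids
  diagonal bridging of adjacent condensates. Phase-contrast cells are
  segmented the same way on the inverted image; low-solidity components
  (usually merged touching cells) are flagged in the mask provenance, not
  split.
* **Demixing counts**: within each condensate the client channel is
  smoothed and local maxima are kept if their height exceeds
  min + fraction × (max − min) of the in-condensate dynamic range and their
  pairwise separation is at least a configured minimum. The separation is
  enforced with a disk-shaped suppression footprint so it is Euclidean, not
  Chebyshev. True topographic prominence is not computed; the dynamic-range
  height criterion is the package's concrete realization of "spot
  detection", with all parameters exposed. The in vivo variant restricts
  counting to condensates above a minimum area-equivalent diameter
  (interpreting the "larger than 1 μm" cut as area-equivalent diameter).
* **Membrane leakage**: a cell is leaky if its dye intensity exceeds
  fold_threshold (default 5) × the median of the healthy reference
  population; the fraction is reported in percent with a 95% Wilson
  interval.

All binomial proportions in the package carry Wilson score intervals.

## Population statistics and assay utilities

* **Filamentous fraction** uses strict inequality (> 4 μm by default).
* **Two-sample tests** default to Welch (unequal variances), since group
  sizes in these experiments are rarely matched; pooled-variance is a flag.
  The lognormal family is exactly the same test on log-transformed values.
  No multiple-testing correction is applied by default (pairwise p-values
  are reported as such); a Bonferroni correction is a caller-side division.
* **Ionic strength** I = ½ Σ c_i z_i² over fully dissociated ions, in mM.
  KCl, NaCl, MgCl₂, CaCl₂ have presets; zwitterionic/partially ionized
  buffers (Hepes, Tris) are treated as neglected and contribute zero, which
  reproduces the standard hand calculation for Hepes-buffered imaging
  buffers (100 mM KCl + 5 mM MgCl₂ → 115 mM; 108 mM KCl + 5 mM MgCl₂ →
  123 mM). ATP speciation conventions vary, so ATP (or any other species
  without a preset) must be entered with explicit charges.
* **Growth rate** is the least-squares slope of ln(OD) vs time, over a
  user-set index window or the contiguous window (≥ 4 points) maximizing R²
  with a slight preference for longer windows among ties.

## Synthetic-data generators

Every generator is a pure function of its parameter object (seed included):
same parameters, bit-identical output; with noise disabled the rendered
images equal their analytic expectations exactly. What they emulate, and
what they deliberately do not:

* **Trajectories**: per-axis Gaussian increments of variance 2DΔt, mixture
  components assigned per track, reported positions = true + N(0, σ²) per
  axis. Confinement is elastic radial reflection at a spherical boundary —
  the simplest model producing the plateaued displacement CDF that must be
  distinguished from free diffusion; the real microdomain's geometry and
  potential are unknown, and the default confinement radius is a
  placeholder, not a measured quantity. No PSF, motion blur, drift, or
  tracking errors are simulated (localization and fiducial-based drift
  correction are upstream of this package).
* **Condensate fields**: hard disks with expected intensity
  background × (1 + E) inside, Poisson photon noise plus optional Gaussian
  read noise, gain 1 (qualitative EMCCD emulation; no gain register or
  excess noise factor). Disks never overlap (rejection-sampled placement);
  real condensates touch, fuse and sit out of focus — passing recovery tests
  here shows estimator correctness, not robustness to those conditions.
* **FRAP movies**: bleached-condensate expected trace
  P·[(1−d) + d·f_m·(1 − e^{−(t−t_b)/τ})]·e^{−k_fade·t} after the bleach,
  P·e^{−k_fade·t} before; a control condensate carries the fade only; the
  field sits on a constant camera offset. A single-τ reaction-dominant
  recovery is the minimal ground truth a fitter can recover; no spatial
  recovery profile is rendered inside the condensate.
* **Cell populations**: horizontal rods (rectangle + semicircular caps,
  width 0.7 μm) on a non-overlapping row layout; body lengths lognormal
  (median 2.2 μm, σ_log 0.18), a configurable filamentous subpopulation
  lognormal around 8 μm (σ_log 0.25) — chosen so the body distribution sits
  well below and the filamentous scale well above the 4-μm rule; polar
  clusters are Gaussian spots whose peak is fold × diffuse level, snapped to
  pixel centers so noise-free peaks are exact. Real micrographs have tilted,
  curved, touching cells and uneven illumination; the phase segmenter's
  merged-cell behavior is therefore only flagged, not solved.
* **Demixed condensates**: channel A as above; channel B holds k Gaussian
  spots per condensate (k from a configurable distribution) placed by
  rejection with a minimum pairwise separation, which must exceed 2 × the
  spot σ so spots are resolvable by construction.

## Problem sizes in the shipped tests and acceptance script

Diffusivity recovery uses 2000 tracks × 10 frames (~18,000 lag-1
displacements) for the single component and 1500 × 10 (~13,500) for the
two-component mixture; FRAP sweeps the 3 × 2 grid f_m ∈ {0.2, 0.5, 0.8} ×
τ ∈ {5, 20} s at 100 frames; enrichment uses 50 condensates at E = 3 with
Poisson noise (in-condensate SNR ≈ 15); demixing uses 200 condensates with
P(k=2) = 0.6; population statistics use n = 2000 lengths and n = 1000 cells.
These sizes put sampling error comfortably inside the tolerances being
checked while keeping a full run on one CPU around half a minute.

## Known limitations

* The CDF fit assumes isotropic diffusion and a known, spatially constant σ;
  anisotropic precision (larger axially) is carried in the tables but not
  used by the 2D fit.
* Segmentation thresholds are Otsu by default for reproducibility;
  low-contrast images that needed manual thresholding in practice should use
  the fixed-level mode, and the chosen level is recorded in the output
  provenance.
* The demixing spot detector's height criterion is per-condensate dynamic
  range, which fails gracefully (counts the brightest spot) but can
  undercount when two spots differ more than the prominence fraction.
* `ionic_strength` is the ideal-dilute formula; no activity corrections.
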