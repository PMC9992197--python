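# Methods

This note documents the models, conventions, and parameter choices behind
`corespec`, and what the synthetic-cohort tests do and do not establish
about real MEG data.

## Study design emulated

Three groups — CI (patients with cognitive impairment, FSIQ < 90), CNI
(patients without, FSIQ > 90), HC (healthy controls) — of 24 subjects
each.  Per subject: a resting-state magnetometer recording, an analysis
segment of 30 s, source reconstruction, and relative spectral power in
eight bands over 26 bilateral Desikan–Killiany ROIs spanning the default
mode, central executive, and salience networks.  A shared empty-room
recording provides the noise covariance.

## Synthetic cohort generator

The generator is the package's ground truth, not a physiological model.
Design choices:

* **Source signals.** Each cortical vertex carries unit-variance 1/f
  background noise (spectral exponent 1, synthesized in the frequency
  domain, amplitude floor at 1 Hz, scaled to 10 nA·m RMS) plus one
  band-limited Gaussian oscillator per analysis band.  Oscillators are
  *coherent within an ROI* (a single waveform shared by the ROI's
  vertices), emulating local field coherence; backgrounds are independent
  per vertex.  Band-limiting is exact (frequency-domain synthesis), so
  every unit of oscillator variance is attributable to exactly one
  analysis band; the inter-band gaps (4–5, 7–8, 12–15 Hz) receive only
  1/f background.
* **Oscillator amplitudes** (RMS dipole moment, nA·m): delta 8, theta 7,
  alpha 10, beta 4, gamma1 2, gamma2 1.5, ripple 1, fast ripple 0.8 — a
  resting spectrum with an alpha peak and a declining high-frequency
  tail, at the ~10 nA·m scale of cortical patch sources.  Group effects
  multiply these amplitudes per (group, ROI, band); the default effect
  map raises patient delta (CI ×1.5, CNI ×1.3), adds a CNI theta
  elevation (×1.3), lowers patient alpha (×0.7), and lowers beta-and-above
  amplitudes (×0.7) in the insula, superior/middle temporal, and
  parahippocampal regions — the direction of the findings this class of
  study reports.  `null_effect_map()` (all multipliers 1) makes the
  groups exchangeable; `planted_effect_map()` modifies a single cell.
* **Sensors.** Quasi-uniform Fibonacci winding on an upper spherical cap
  (polar angle ≤ 115°) of radius 1.1 × head radius (9 cm), radially
  oriented magnetometers.  White sensor noise of 0.2 pT RMS per sample
  (≈ 10 fT/√Hz at the 600 Hz desk rate) and a 1 pT, 50 Hz line component
  with random phase per channel.
* **Source space.** A spherical shell at 0.78 × head radius.  Half the
  vertices are quasi-uniform on the right hemisphere and labeled by
  nearest of 13 patch centers (contiguous Voronoi patches); the left
  hemisphere is their exact mirror across x = 0, so bilateral ROI
  geometry is symmetric by construction.  *Normals are tilted 60° from
  radial toward the local azimuth*: purely radial dipoles are silent in a
  spherical conductor, so some fixed tangential component is required for
  the ROIs to be visible at all; 60° keeps a dominant tangential part
  while remaining "outward".  Gyral folding, vertex-level orientation
  disorder, and cortical geometry are deliberately absent.
* **Clinical covariates** are independent truncated Gaussians with the
  published group means/SDs (FSIQ truncated to < 90 for CI, > 90 for CNI;
  HC WISC indices modeled as N(100, 5²) truncated to the stated 90–110
  normal range; course and seizure count truncated at 0; onset age to the
  4–14 y syndrome range).  Seizure count is kept continuous so the
  published mean/SD are matched; no covariance structure between
  covariates is modeled because none is published.
* **Determinism.** One master seed drives everything through
  `numpy.random.SeedSequence` spawning; an identical design reproduces a
  bit-identical cohort, and per-subject streams are independent.

## Desk-scale study conditions

Correctness does not require acquisition-scale data, so the default
profile is desk-scale: 64 sensors, 600 Hz sampling, 60 s recordings, 520
vertices.  The acquisition-scale profile (275 sensors, 6 kHz, 120 s,
15 000 vertices) is available via `CohortDesign.paper_scale()`; vertex
synthesis is chunked so memory stays bounded at any size.  The repeated
cohort experiments use further-reduced sizes chosen for throughput: null
calibration uses 8 subjects/group, 78 vertices, 60 s; the twenty
planted-effect cohorts use 24 subjects/group, 52 vertices (2 per ROI),
32 s recordings.  At 600 Hz the fast-ripple band (250–500 Hz) exceeds
Nyquist and is dropped with a logged warning; the relative-power
denominator then spans the remaining seven bands.

## Preprocessing

* **Notch**: order-2 Butterworth band-stops of 2 Hz bandwidth at 50 Hz
  and every harmonic below Nyquist, applied forward-backward
  (zero-phase).  The steady-state attenuation at the line frequency is
  far beyond 40 dB; edge transients of the forward-backward pass are the
  only residual.
* **Segment selection** replaces visual artifact screening with an
  explicit rule: the first 30 s window in which every channel stays below
  a per-channel amplitude threshold.  The default threshold is 10× the
  channel's median absolute deviation (≈ 6.7 σ for Gaussian data).  A
  stricter multiplier like 5× MAD (≈ 3.4 σ) is exceeded hundreds of times
  by ordinary Gaussian fluctuation over minutes of data and would reject
  every recording; 10× keeps the false-alarm probability negligible while
  catching genuine bursts, which in practice sit orders of magnitude
  above baseline.  No clean window raises an error, never a silent
  truncation.
* **Noise covariance**: sample covariance of the demeaned empty-room
  channels, shrunk toward its diagonal by 0.1 to guarantee positive
  definiteness at desk-scale durations (shrinkage 1 gives an exactly
  diagonal matrix).

## Forward model

A single best-fit conductor sphere (algebraic least squares through the
vertex cloud, radius inflated 10 % to contain all vertices) with the
Sarvas closed-form field of a current dipole in a homogeneous conducting
sphere, projected onto each sensor's orientation; dipole orientations are
fixed to the vertex normals.  With the synthetic spherical source space a
single sphere and per-sensor overlapping spheres coincide; the
`HeadSphere` parameter of `compute_lead_field` is the hook for per-sensor
spheres on real geometry.  Degenerate cases (dipole at the center, radial
moments) resolve to the analytic zero-field limit, never to non-finite
output.  Units are SI throughout: meters, A·m, tesla.

The forward model is verified against an independent numerical oracle:
the primary dipole's Biot–Savart field plus the volume-current
contribution reduced to a Geselowitz surface integral over the boundary
potential, the latter from a Legendre-series solution of the insulated
conducting sphere's Neumann problem.  Agreement is ~5 × 10⁻⁴ relative,
far inside the 2 % tolerance used by the tests; the radial field of a
tangential dipole also matches the primary term alone, confirming that
volume currents contribute no radial component.

## Inverse operator

Depth-weighted minimum norm with fixed orientations.  Conventions, all
config-exposed:

* depth weights w_s = ‖g_s‖^(−2γ), γ = 0.5, with the largest weights
  clipped so max(w)/min(w) ≤ limit² (limit 10) — the conventional
  distributed-MNE defaults;
* prior R = ν·diag(w) scaled so trace(L R Lᵀ)/n_sensors = 1 with
  L = C^(−1/2)G, which makes λ² the reciprocal of the power SNR; the
  default λ² = 0.33 therefore asserts SNR ≈ 3.  Whitening uses the
  symmetric eigendecomposition square root.  Other packages' internal
  whitening/normalization conventions may differ; ours is declared, not
  claimed identical to any of them.

The kernel is checked to 10⁻⁸ relative against a dense normal-equations
solve of the penalized least-squares problem on random instances, reduces
to G⁻¹ in the unregularized square case, and its application is streamed
over time blocks with bit-stable results.  On a multi-depth test cloud,
depth weighting (γ = 0.5) roughly halves the mean superficial
localization bias relative to γ = 0 (≈ +9 mm → +4 mm on 20 random
dipoles).

## ROI spectra

Welch PSD with Hann taper, density scaling, 5 s windows, 50 % overlap
(0.2 Hz bins).  ROI reduction is *power-first*: PSD per vertex, then the
mean across the ROI's vertices.  Averaging time series first
(`reduction="mean"`, kept for comparison) suffers phase cancellation —
two anti-phase vertices cancel exactly — which is why power-first is the
default.  Band powers are sums of in-band bins times the bin width; band
edges are inclusive except that a bin on a shared edge (90 Hz, 250 Hz)
counts once, toward the lower band.  Relative power divides each band by
the summed power of the analyzed bands only (gap bins are excluded from
numerator and denominator alike), yielding rows in [0, 1] that sum to 1
and are invariant to any global amplitude rescaling — so the unknown
overall source-unit scale of the inverse never matters downstream.

## Statistics

Per (ROI, band): Kruskal–Wallis across the three groups (tie-corrected H,
chi-square reference; an exact enumerated permutation p is available for
total n ≤ 14), then pairwise Mann–Whitney contrasts with Bonferroni ×3.
BH-FDR is applied across the 26 ROIs within each (band, contrast) family,
matching per-band reporting; correlations of onset age, course, and
seizure count with each (ROI, band) cell within each patient group use
Pearson when both variables pass a Shapiro–Wilk gate (α = 0.05) and
Spearman otherwise, FDR-corrected within each (group, covariate, band)
family.  Two multiple-testing systems coexist deliberately: Bonferroni
*within* a cell's three pairwise contrasts, FDR *across* ROIs.  Summary
t-tests (Welch by default, pooled available) reproduce the published
clinical group differences as bounds (p < 0.001 for FSIQ/VCI/PRI/WMI).

Degenerate-input conventions: all-identical samples give H = 0, p = 1;
constant samples are flagged degenerate by the normality gate rather than
crashing; zero-variance correlation inputs are errors.

One numerical convention worth stating: the exact Kruskal–Wallis
permutation p defaults to the conservative P(H ≥ h).  When *comparing*
the discrete permutation null against the continuous chi-square reference
the tests use the Lancaster mid-p (P(H > h) + ½P(H = h)); with the
conservative convention the mean gap at n = (4,4,4) is 0.030 — a property
of the chi-square approximation itself — while the mid-p comparison gives
0.018.

## Calibration and recovery results the suite computes

* Null calibration: with all multipliers 1, the per-cell KW rejection
  rate over 546 cells (three 8-per-group cohorts) lands near the nominal
  0.05 (bounds [0.02, 0.10] in the test).
* Effect recovery: a ×2 delta multiplier in PCC.L for CI (24/group) puts
  (PCC.L, delta) in the CI–HC FDR rejection set in ≥ 18 of 20 seeded
  cohorts, with delta up and alpha down in every one.  Inverse leakage
  also flags immediate neighbors — expected behavior of distributed
  source estimates, not a defect.

## What passing tests do and do not show

The generator shares the analysis model's geometry (spherical head,
normal-oriented dipoles, white sensor noise), so these tests verify the
*computational chain* — forward/inverse algebra, spectral estimation,
normalization, statistical calibration — under conditions where the truth
is known.  They do not validate the spherical conductor against real
heads, the 1/f-plus-oscillator model against real neural spectra, head
movement, ocular/cardiac artifacts, or epileptic spike morphology (spike
avoidance is emulated only as amplitude thresholding).  Published
patient-data p-values depend on recordings that are not deposited and are
not reproduced here; the package reproduces the procedure and its
calibration, not those numbers.

## Known limitations

* Single-sphere conductor and shell source space; no BEM/FEM, no real
  cortical geometry.
* Fixed-orientation MNE only (no dSPM/sLORETA, no loose orientations).
* One 30 s segment per subject is analyzed; multi-file concatenation is
  out of scope.
* The FDR family and the Bonferroni/FDR interplay follow the per-band
  reading documented above; a global family is a config option.
* Correlation signs are reported as computed; no directional claim is
  built in.
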