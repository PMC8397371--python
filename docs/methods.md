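# Methods

## The measurement model

A hybrid micropatterned substrate presents ligand in micron-scale circular
corrals of two kinds under one cell: corrals on a fluid supported membrane,
whose ligand the cell's receptors can drag into a cluster ("mobile"), and
corrals of polymer-grafted ligand that cannot rearrange ("immobile").
Photoswitchable adaptor proteins are imaged at sparse activation so that
individual membrane-binding events appear, move, and disappear as
diffraction-limited spots in a TIRF movie (20 frames/s, 1000 frames,
~0.5 active molecules/µm²). Analysis proceeds: detect → link → mask by the
pre-acquired ligand channel → dwell-time survival per region → two-order
exponential fit → paired mobile-vs-immobile comparison per cell.

### Dwell-time model

Observed single-molecule residence times are modeled as a two-component
exponential mixture. The fast component (τ1 ≈ 60–80 ms at 50 ms frames)
absorbs short-lived fluorescence events and transient excursions of
cytoplasmic molecules through the evanescent field; the slow component τ2
characterizes membrane binding and is the comparison statistic (apparent
K_off = 1/τ2). The fitted curve is the empirical survival function
S(t) = fraction of molecules with dwell ≥ t, evaluated on the frame grid
t = k·dt, not a binned histogram — survival is bin-free and the estimator
the decay model describes. Because a molecule visible during any part of a
frame occupies that frame, the quantized survival at k·dt equals the
continuous survival at (k−1)·dt; the shift is absorbed exactly by the
amplitudes, so quantization does not bias the time constants.

Points where fewer than 0.5% of molecules remain are excluded before
fitting: the extreme tail is dominated by counting noise and represents
under half a percent of the data.

### Fitting choices

`fit_two_exponential` implements the decay form
y0 + A1·e^(−t/τ1) + A2·e^(−t/τ2) by bounded nonlinear least squares with
five jittered multi-starts and best-RSS selection; components are
canonically ordered (τ2 ≥ τ1) afterwards. Two options matter and their
defaults differ between the raw primitive and the dwell-sample path:

* **Offset y0.** A survival function decays to zero by construction, so
  `fit_dwell_sample` pins y0 = 0. Left free, y0 trades against the slow
  component and biases τ2 low by 4–6% when τ2/τ1 ≲ 3 (measured at
  τ2 = 140–150 ms, τ1 = 60 ms, n = 10,000). A free offset is only
  meaningful when fitting a histogram with a noise floor, and remains
  available (`fix_y0=False`).
* **Weighting.** Survival points have binomial sampling error
  ∝ √(S(1−S)); weighting residuals accordingly removes most of the
  remaining variance at closely spaced time constants. With both options
  the median relative error of τ2 is ≤ 4.2% at the hardest condition
  (140 ms), against 3–4% for a maximum-likelihood fit of the quantized
  mixture on the same draws — i.e. the weighted survival fit is close to
  the information limit. Unweighted fitting (`weighted=False`) reproduces
  the plain decay fit.

### Photobleaching

Bleaching truncates every dwell: with bleach rate k_b the apparent slow
constant is exactly 1/(1/τ2 + k_b), since the bleach time is an independent
exponential. A membrane-anchored control fluorophore measures k_b by a
single-exponential survival fit (`fit_photobleach_control`). The package
reports k_b next to τ2 and offers `corrected_koff = 1/τ2 − k_b`, but never
applies the correction silently: absolute unbinding cannot be reliably
deconvolved from bleaching in live-cell data, whereas the mobile/immobile
*ratio* of apparent constants is nearly bleach-invariant, which is why the
paired within-cell design works.

### Association rate

K_on(region) = (# trajectory first appearances in region) / (region area ×
movie duration), optionally divided by the region's mean ligand intensity
(`normalize_by_ligand`) — the per-area and per-ligand conventions are both
legitimate readings of the normalization and both provided.

## Detection and tracking

Candidates are local maxima of the cross-correlation between the frame and
a zero-mean, unit-norm Gaussian template of the PSF width (a matched filter
whose response is in amplitude units, hence offset-invariant). The noise
level is a one-sided median-absolute-deviation of the response taken on
negative deviations only, because emitters push the response only upwards;
the default threshold is 5× that level. Candidates are refined by a
least-squares 2-D Gaussian with free width and constant background, run as
a damped Gauss-Newton over the whole candidate batch at once (a per-spot
scipy fit is ~50× slower at 10⁵ spots; the batch fitter is cross-checked
against `scipy.optimize.curve_fit` in the test suite). Width-at-lower-bound
fits are discarded as noise. Wide fits (≥1.25 σ_psf) are refit with two
fixed-width Gaussians and split when that halves the residual — at
0.5 molecules/µm² a wide fit is usually two just-overlapping single
molecules, not an aggregate; only wide fits that also fail the split are
discarded as aggregates. Measured on rendered frames at the study density:
recall 0.97, precision 1.00, localization RMS ≈ 0.11 px/axis at 500
photons.

Linking is greedy nearest-neighbor: candidate (track, localization) pairs
sorted by distance, accepted when both are free and the distance is within
`max_disp`. At unambiguous densities this equals the optimal bipartite
assignment (property-tested against the Hungarian algorithm). The default
`max_disp` is 2·σ_psf: confined motion moves a molecule ≲0.4 px between
frames, and widening the gate to 4·σ admits mostly death→birth chaining
and neighbor captures (link identity drops from 99.2% to 98.3% at the
study density). `gap_max` (default 0) closes detection dropouts; rendered
movies lose ~3% of detections per frame to overlap, so end-to-end runs
use `gap_max=1` to avoid splitting long dwells.

A dwell is (observed frame span) × dt with gap frames counted, so a
single-frame appearance dwells one frame interval. Tracks touching the
first or last movie frame are flagged censored and excluded from fits.

## Region masks

Segmentation thresholds the ligand channel globally with the lowest cut of
a three-class Otsu computed on smoothed log intensity. A two-class Otsu
fails structurally on these images: a clustered (mobile) corral concentrates
most ligand into one punctum, leaving its body ~10× dimmer than an immobile
corral, and the two-class threshold then falls between the corral
populations. Components are filtered by area ([0.5, 2]× the expected disk)
and circularity (≥0.6), refined by the same threshold on the raw image so
the smoothing does not inflate areas, and dilated by one pixel to capture
rim-trapped clusters (recorded areas are pre-dilation). Mobility is
classified by a clustering index — 99th-percentile over mean intensity
inside the corral (≈1 for uniform, ≫1 for clustered; threshold 3.0) — and
is invariant to multiplicative gain. A user-supplied mask or layout always
overrides the automatic segmentation, which reconstructs what was
originally a manual outlining step.

A trajectory's region is the mask label at its *first* appearance — the
binding location defines the signaling region and matches the
localization-image convention.

## The synthetic-data generator

The generator is the ground truth for every test: arrivals per corral are
a homogeneous Poisson process (rate k_on × corral area), dwells are drawn
from the two-exponential mixture in continuous time, bleach times are
independent exponentials, and the observed dwell is the minimum of dwell,
bleach and remaining movie. Motion is reflected Brownian inside a
confinement disk around the binding site (D = 0.01 µm²/s, radius 0.15 µm
for mobile regions — adaptors bound to clustered receptors are confined
well below the diffraction limit; immobile regions are static). Rendering
stamps pixel-integrated Gaussians (500 photons/frame, σ = 1.0 px at
0.10 µm/px), adds Poisson shot noise over a 20-count background and 3-count
read noise, with an optional doubled-shot-variance switch approximating
EMCCD excess noise (off by default). The ligand channel conserves total
intensity per corral (density × area) and places the mobile-corral punctum
at a uniformly random angle, 0.7 r from the center, reflecting rim-trapped
clusters.

Frame quantization happens only at analysis time (`quantize_dwells`),
keeping the generative truth independent of acquisition settings. All
randomness flows from one integer seed; identical seeds give bit-identical
event tables and movies.

What the generator does **not** emulate: cell spreading and contact
dynamics, receptor endocytosis, force-driven cluster transport, spatially
varying autofluorescence, EMCCD gain registers, or dwell-time correlations
between molecules. Passing tests therefore demonstrate that the analysis
recovers known kinetics under the stated noise model, not that it is
robust to every artifact of live-cell data.

## Problem sizes and numerical choices

* Dwell-recovery checks use 10,000 dwells per condition and ≥20 seeds;
  the reported value is the across-seed median.
* End-to-end movie checks use a 4×4 alternating layout (radius 2 µm,
  spacing 5 µm, 200×200 px), 1000 frames at 20 frames/s, ~0.5 active
  molecules/µm² inside corrals.
* Fold-change quantifications run at the study's sample sizes (26, 15, 19
  cells; 103 vs 82 cells for the nuclear measure) and average a handful of
  replicate experiments because a single experiment's sampling error at
  those sizes (2–7% of the fold) is comparable to the recovery tolerance.
* Change-point selection for photobleach steps uses a per-step penalty of
  6·ln(n)·σ̂² — stiffer than the classical 2·ln(n) because the change point
  is optimized over all positions, which inflates the best chance RSS
  reduction on stepless traces; real bleach steps exceed either penalty by
  orders of magnitude.
* Degenerate inputs: empty dwell samples, empty masks, all-zero images and
  zero-variance paired differences are reported with explicit flags or
  errors rather than NaNs (e.g. identical pairs → t = 0, p = 1; constant
  nonzero differences → p < machine precision with a `zero_variance` flag).

## Known limitations

* The two-exponential form is an operational summary; it does not separate
  unbinding from bleaching and underestimates rare very long dwells that
  bleach before ending.
* Greedy nearest-neighbor linking has no motion model; above
  ~1 molecule/µm² identity errors grow quickly.
* Corral segmentation assumes bright-on-dark disks of roughly the expected
  size; irregular or merged corrals need a user-supplied mask.
* Nuclear masks are inputs; no nuclear segmentation is provided.
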