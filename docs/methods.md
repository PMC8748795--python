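# Methods

## Coordinate and unit conventions

Pixel coordinates are 0-based `(row, col)` with pixel centres at integer
coordinates. Arc length is measured in µm along a hypha's midline from its
first point; straightening resamples the midline uniformly from end to end,
so the sample spacing is `arc_length/(n−1)`, marginally under one pixel.
Intensities are arbitrary units (AU); times are minutes; lengths µm. Pixel
size (default 0.1 µm/px) and frame interval (default 10 min) are supplied
by config, never parsed from TIFF tags, whose dialects vary; when both are
present and disagree, config wins with a logged warning.

## The measurement chain

**Registration** is rigid translation only, estimated per frame against
frame 0 by phase cross-correlation at 1/20-px resolution and applied with
bilinear interpolation; out-of-canvas pixels are filled with the frame
median. Rotation/deformation correction is out of scope: the data this
targets are short windows around growth cessation where drift is planar.
Zero-variance frames get zero shift and a warning.

**Background correction** computes multi-Otsu thresholds (3 classes by
default: background / cytoplasm / septal signal) on the intensity
histogram; pixels at or below the lowest threshold are the background
class, whose mean (median by flag) is subtracted from every pixel, clipped
at zero. Degenerate rasters fall back to fewer classes; a constant raster
maps to zeros. Correction is applied per frame (whether a per-frame or
per-series correction is more faithful to common practice is debatable;
per-frame is implemented and flagged in the API).

Two refinements matter for quantitative use and are exposed as options:

- *No clipping for ROI averaging* (`clip=False`). Clipping at zero biases
  the mean of noisy dim regions upward by roughly +0.4 σ per pixel; kinetic
  traces therefore use unclipped subtraction.
- *Stack-level correction* (`background_correct_stack`) segments the
  background **region** once on the average projection — where background,
  cytoplasm and rings are all represented and the class structure is well
  defined — then re-estimates only the background **level** per frame as
  the median over that fixed region, with the top decile of the class (the
  threshold-adjacent pixels, where dim foreground leaks in) trimmed off.
  This keeps the correction per-frame while avoiding threshold instability
  on frames whose histogram is nearly two-class (e.g. after all rings have
  disassembled).

**Straightening** maps the band `±half_width` px around the midline into a
straight raster by bilinear interpolation along unit normals of the
resampled midline. The "5 pt" profile line convention is implemented as a
5-px transverse averaging band (`half_width = 2`), configurable.

**Kymographs** freeze the midline at its final-frame trace for all rows:
rings assemble in the non-growing tip compartment after cessation, where
the midline no longer moves. Per-frame midlines were considered and
rejected for scope.

**Ring detection** finds local maxima with strict neighbour comparison
(flat-topped peaks report the middle sample, rounded down; profile ends are
never peaks), removes peaks with apex intensity below 100 AU — the fixed
false-positive filter, applied to background-corrected profile values;
whether the filter should test apex height or prominence above baseline is
ambiguous, so apex height is the default with prominence as an option —
then merges survivors closer than 3 samples keeping the higher apex
(leftmost on equal apexes). The filter threshold only has its intended
meaning when cytoplasmic profile levels are sub-threshold, which the
simulator's default cytoplasm level (60 AU) respects.

**FWHM width** uses a local baseline: the minimum of the two
flanking-valley intensities (nearest local minimum each side, or profile
end), robust to cytoplasmic fluorescence; a zero-baseline flag exists for
sensitivity analysis. Half-level crossings are located by linear
interpolation between samples; a peak whose half level is never crossed on
one flank (typically at a profile edge) is **censored** — counted, but
excluded from width statistics. On sampled Gaussian bands the estimator is
within 2% of 2√(2 ln 2)·σ at 1-px sampling for σ ≥ 2 px.

**ROI kinetic traces** average a 10 × 20 px window — 10 px along the hypha
axis, 20 px across (the convention chosen here; only the ROI size is
standard) — centred on the ring position in straightened coordinates, per
frame. Traces can be averaged frame-by-frame or aligned on detected
fluorescence onset (first frame above 20% of dynamic range); both modes
exist because published trace figures do not always state their alignment.
Point-wise s.e.m. uses n−1; time points covered by one trace get s.e.m. 0.

**Replicate statistics** pool widths (censored excluded) and within-hypha
spacings per replicate and report means with two-sided 95% CIs from the
t-distribution with n−1 degrees of freedom.

**Cross-wall regression** is OLS of count on length with intercept
(through-origin by flag); fits are produced per replicate and pooled, since
published per-figure practice varies. Mean spacing = 1/slope, defined only
for positive slope. All-zero counts short-circuit to slope 0. With
exponential gaps the placement process is Poisson, so E[count] = L/mean gap
exactly and the intercept is 0 in expectation.

**Spore histograms**: the instrument's "0.6–18 µm" range is a
spherical-equivalent **diameter** range; bins are 400 log-spaced intervals
over the corresponding volume range (π/6·d³), with a diameter-log-spacing
option (identical edges up to floating point). Out-of-range particles are
excluded from normalization — an aperture cannot see them — and reported.
Bin edges are log-spaced but serialized as plain full-precision columns so
downstream plots on a linear axis reproduce them exactly (CSV reads should
use round-trip float parsing). Titre = (aliquot count / 50 µl) × 500.

## The simulator

The generator's goal is data with the statistical structure the analyses
assume, not photorealism (no PSF/optics model, no 3-D, no branching
morphogenesis).

**Movie model.** A hypha is a transverse Gaussian ridge (FWHM =
`hypha_width`, default 0.8 µm) along a gently undulating midline (±2 px,
period 250 px) on a planar background (20 AU + 0.02 AU/px tilt). The tip
extends at 0.3 µm/min until `growth_cessation_frame`; with the default
24 frames × 10 min (one pre-cessation frame), that is a 240-min window.
After cessation, a ladder of septal rings appears in the distal
`ring_zone_length` = 10 µm tip compartment with gaps ~N(1.3, 0.15²) µm;
each ring is an axial Gaussian of s.d. `ring_axial_sigma` whose amplitude
follows a piecewise-linear rise (to `ring_amplitude` over
`ring_rise_time`) then fall (over `ring_fall_time` = 80 min) — published
trace figures show rise-to-peak-then-decay without a functional form, so
the simplest shape with controllable timescales is used. Ring truth
positions live in the same polyline arc coordinate the analysis measures.
Onsets share a common post-cessation frame ±1 frame for every preset;
per-ring independent timing is available via `ring_onset_jitter_frames`
but is not what distinguishes the presets, so that the `wt_like` /
`mutant_like` contrast is attributable to exactly three parameters:
amplitude (800 vs 500 AU), axial sigma (0.20 vs 0.22 µm — the injected 10%
width effect), and rise time (40 vs 90 min).

**Biological heterogeneity.** Rings in one hypha scatter lognormally in
mature amplitude (CV 0.15), and the cytoplasmic level is modulated along
the arc by a smooth lognormal field (10% relative s.d., 3 µm correlation).
Without these, all rings are statistically identical and the across-ring
s.e.m. collapses to pure pixel noise — an unrealistic regime in which
mean ± s.e.m. bands are meaninglessly narrow; real trace figures derive
their width from exactly this ring-to-ring variability.

**Noise** is Gaussian shot noise with variance proportional to signal
(scale 0.5) plus additive read noise (σ = 3 AU), with optional exponential
bleaching; no imaging-system characterization exists to fit against, so
the defaults are conventional values that leave the analyses noticeably
but not pathologically perturbed. Randomness is split into independent
placement and noise streams per seed, so rendering the same truth with and
without objects consumes identical noise draws, and all outputs are pure
functions of (config, seed).

**Cross-wall snapshots** lay hyphae out as horizontal filaments (lengths
uniform in 50–500 µm: 5–6 h of growth including branches), with septa
placed by a Poisson process of mean gap `crosswall_spacing_mean` (25 µm;
12.5 for the doubled-rate preset; ∞ for the deletion-like preset) and
rendered as bright transverse bands (axial σ = 0.15 µm). Long canvases
emulate stitched tiled acquisitions: the illumination gradient restarts
every 512 px rather than accumulating over a canvas whose width scales with
hyphal length — no real acquisition has a kilopixel-scale monotone ramp.

**Particle samples** are log-normal volume draws (the simplest strictly
positive unimodal family for particle sizes); defaults in the analysis
drivers are log-mean 0 / log-sd 0.25 (≈1 µm³ spores) for the normal
population and log-mean ln 1.6 / log-sd 0.45 for the larger, more variable
division-mutant-like population.

**What passing tests do and do not show.** Recovery on these simulations
demonstrates that the estimators are correct and unbiased under the stated
generative model at realistic noise. It does not validate performance
against optical blur (no PSF), midline tracing error (truth midlines are
exact), focus drift, branching, or ring movement along the hypha — all of
which real data contain.

## Numerical choices and degenerate inputs

- Peak ties and plateaus: plateau middle (rounded down) is the apex; equal
  apexes within the separation window keep the leftmost.
- Censored rings propagate as NaN widths with a flag, never silently.
- Constant rasters: background correction returns zeros with a log note;
  zero-variance frames register with zero shift and a warning.
- Minimum physical ring gap clamps placement at 0.3 µm so jitter cannot
  produce coincident rings.
- Seeds are consumed in a fixed order (onset jitter, amplitude factor, gap
  per ring; then the cytoplasm field; then noise), so switching rings off
  (amplitude 0) leaves every other draw unchanged.
- Study sizes in tests and the acceptance script (10 movies, 3 × 20 hyphae,
  10⁴–10⁵ particles, 1000 oracle profiles) were chosen so each estimator's
  sampling error sits well inside its recovery tolerance; the whole suite
  runs in well under a minute of compute.

## Known limitations

- The cross-wall spacing estimator 1/slope is convex in the slope, so for
  small designs it is biased upward (Jensen); at 3 × 20 hyphae the spacing
  ratio between two regimes carries ~11% sampling s.d.
- FWHM on profiles sampled at 1 px is quantized: apex positions carry
  ±half-sample uncertainty, and widths of bands narrower than ~2 px are
  unreliable (and ~5% high at σ = 2 px from discrete sampling).
- The 100 AU filter is meaningful only relative to the imaging system's
  AU scale; on other data it must be recalibrated (it is a flag
  everywhere).
- Dual-channel analysis reports a single Pearson correlation of the two
  profiles; it is a co-localization summary, not a calibrated overlap
  coefficient.
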