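# Methods

This note documents the models, algorithms and default parameters behind
`octmorph`, the choices made where the underlying analysis protocol left the
design open, and what the synthetic phantoms do and do not establish about
real data.

## The NSL statistic

For one B-scan, the tissue surface is a single-valued profile y(x) in
physical micrometres (x lateral, y depth).  Its baseline is the unweighted
ordinary-least-squares cubic of y on x — the cubic *is* the baseline; no
further detrending is applied.  The statistic is

NSL = L_s / L_p,

with L_s the polyline length of the profile and L_p the polyline length of
the fitted cubic *evaluated at the profile's own x samples*.  Using the same
discretization for numerator and denominator removes discretization bias
from the ratio: a profile that is exactly a degree-≤3 polynomial yields
NSL = 1 to 1e-9, regardless of sampling density, and doubling the sampling
of a smooth profile moves NSL by < 0.1%.

The fit runs on a centered/scaled abscissa for conditioning and reports
coefficients in the original coordinates.  Because the OLS cubic is not the
shortest admissible baseline, NSL can fall below 1 for profiles with sharp
high steps (the fitted cubic overshoots and becomes longer than the profile);
such values are reported as-is and flagged with a warning, never clamped.
NSL is computed in physical units: with anisotropic pixels a pixel-space
computation would change the answer, so physical µm coordinates are the
default and only documented path.

Per-mouse aggregation is the arithmetic mean of per-B-scan NSL values.  For
normal-ovary volumes the protocol selects n equally spaced B-scans (default
n = 5) as the centers of n equal partitions of the B-scan axis,
floor((k+0.5)·N/n) — this avoids the degenerate endmost slices.  For tumor
volumes the outgrowth-containing B-scans are listed explicitly in the
manifest.

## Surface tracing

The air/tissue boundary is defined per lateral column as the first depth at
which intensity exceeds a threshold for at least `min_run_px` (default 3)
consecutive pixels; the run requirement rejects isolated speckle spikes in
the background.  Overhangs are flattened to the shallowest crossing, since
the cubic fit presumes a function of x.  Columns without a crossing are
linearly interpolated when the lateral gap is ≤ `max_gap_px` (default 10),
otherwise excluded.  The depth sequence is despiked with a median filter
(default window 5 px).

Two refinements beyond the bare first-crossing rule are enabled by default
and matter for the statistic:

- **Sub-pixel crossing** (`subpixel`): the crossing depth is linearly
  interpolated between the intensities below and above threshold.  This is
  meaningful because a real (and simulated) boundary voxel mixes tissue and
  background signal in proportion to coverage.
- **Lateral smoothing** (`smooth_lateral_um`, default 12 µm Gaussian σ):
  without it, per-column jitter of even ~0.5 px inflates the polyline length
  of a genuinely smooth surface by several percent, because the 3-µm
  segments are short compared to the jitter.  With both refinements, a
  smooth phantom surface at high SNR yields per-mouse mean NSL within 1e-3
  of 1.0, while the roughness response of genuinely folded surfaces is
  preserved (the smoothing σ is small relative to the ~100 µm feature scale
  of outgrowths).

The default absolute threshold (45) sits near the half-level between the
phantom background (5) and tissue (100) intensities, which makes the
sub-pixel crossing estimate unbiased; a percentile form is available and
makes tracing invariant to global intensity scaling.  On real volumes the
threshold must be set against the instrument's intensity scale, or manual
delineations supplied — these always take precedence over auto-tracing.

## Volumetry

"Smoothness level of 5 µm" is realized as a Gaussian filter with physical
σ = 5 µm (σ in voxels = 5/voxel size per axis, reflective borders) — the
closest transparent analog of the proprietary surface-smoothing level in the
commercial tool this mirrors.  Segmentation thresholds are absolute by
default.  Components are labeled under 26-connectivity (default; 6 and 18
available), filtered by a minimum physical volume, and ordered by descending
voxel count.  Object volume is voxel count × voxel volume; digitized spheres
of radius ≥ 10 voxels are recovered within 2% of (4/3)πr³, and phantom
spheroids of radius ≥ 30 µm within 10% (the residual bias is curvature
shrinkage from the 5-µm smoothing).

Dark (hypointense) objects — fluid-filled chambers — are only meaningful
inside tissue, so dark-polarity segmentation is restricted to a tissue mask;
if none is given, one is derived from the smoothed volume itself
(≥ threshold, morphologically closed, holes filled) with a warning.  A
`compartment_mask` helper builds above/below-surface masks from a surface
depth map, which is the recommended restriction when the surface is known.
The ROI route computes shoelace polygon areas × B-scan spacing and agrees
with the voxel route within 10% on spheres spanning ≥ 10 B-scans.

## Group statistics

The normality screen is a one-sample KS test against a normal with mean and
sd estimated from the sample.  Because parameters are estimated, the plain
KS null would be anti-conservative; the null of the D statistic is therefore
the Lilliefors one, obtained by Monte Carlo (10 000 standard-normal samples
per sample size, fixed internal seed, cached) with the add-one estimator
(1 + #{D₀ ≥ D})/(N + 1).  Samples below n = 4 are reported inconclusive
(NaN), zero-variance samples as degenerate (p = 0).  The screen is recorded
but never switches the test: group comparisons always use the two-sided
Wilcoxon rank-sum test, matching a protocol in which no group passed the
screen.

The rank-sum test uses pooled midranks.  For n_a + n_b ≤ 14 without ties
(mode `auto`), the exact two-sided p is computed by enumerating all
C(n_a+n_b, n_a) rank assignments, p = min(1, 2·min(P(W ≤ w), P(W ≥ w)));
exact mode refuses tied data and falls back, with a warning, to the normal
approximation with tie-corrected variance and continuity correction.  At
n = 10 vs 10 the approximation's rejection region coincides with the exact
test's (size 0.0433 at nominal α = 0.05), and simulated type-I rates over
2 000 replicates fall within [0.035, 0.065].

## The phantom generator

The phantom emulates the first-order structure of intravital OCT B-scans of
the mouse ovary at the study's sampling scales (~3 µm transverse sampling,
used isotropically for simplicity; ~6 µm axial resolution is not modeled as
a PSF — see limitations):

- **Surface**: mean depth plus a lateral polynomial trend (degree ≤ 3,
  coefficients about the lateral center) plus, optionally, a Gaussian random
  field with RMS amplitude `roughness_amplitude_um` and correlation FWHM
  `roughness_wavelength_um` (default 100 µm, the scale of the smallest
  resolvable outgrowths, ~88 µm).
- **Attached outgrowths**: spherical caps of radius 40–150 µm merged into
  the surface (minimum of the cap and base depths).  Caps may overlap each
  other — clustered outgrowths merge into one folded surface, which is the
  morphology being emulated; the non-overlap placement contract applies to
  detached spheroids and chambers, which are rejection-sampled to be
  disjoint and fully inside their compartment (error named by class on
  failure).
- **Intensity**: background (default 5) above the surface, tissue (default
  100) below with single-exponential depth attenuation (default 0.004/µm),
  partial-volume mixing at boundary voxels, all multiplied by unit-mean
  gamma speckle with shape `speckle_shape` (default 4; relative SD
  1/√shape).  No intensity statistics were available for the original
  images: speckle shape and attenuation are free, documented choices, not
  measured values.  An optional thin elevated-intensity sheet 30 µm above
  the surface mimics the ovarian bursa as a scene element only.
- **Ground truth**: the exact analytic surface map and every object's
  center, radius and analytic volume ((4/3)πr³ for balls; undefined for
  merged caps) are returned and written as CSV sidecars next to the
  multi-page TIFF.

Identical spec + seed gives bit-identical volumes.  In pipeline runs one
global seed expands into per-phantom sub-seeds via `SeedSequence`.

**What the phantoms do not show.**  They contain no coherent PSF, speckle
correlation, refraction, sensitivity roll-off, follicle substructure or
tissue-class texture.  Passing tests therefore establish the correctness and
calibration of the *computations* (tracing, NSL, volumetry, statistics) under
controlled ground truth — not that the tracer or thresholds are optimal for
any particular instrument's images.

## Problem sizes and numerical choices

- Cohort phantoms for end-to-end runs are 600 × 480 µm × 10 B-scans
  (200 × 160 px); volumetry phantoms 600 × 600 µm × 110 B-scans.  These sizes
  keep full 100-repetition cohort simulations cheap while leaving ≥ 60 µm of
  headroom around every scene object.
- Smoothing and median filters use `nearest`/`reflect` boundary handling;
  Gaussian smoothing of volumes conserves interior mass to 1e-6.
- Ties in manual profiles (duplicate x) are collapsed by averaging y before
  fitting; profiles with < 4 distinct lateral positions are rejected
  (`InsufficientProfileError`) since the cubic design would be rank
  deficient.
- Result tables are CSV at 12 significant digits (round trip to ~1e-9
  relative); 0-based indices are used everywhere in files and on the CLI.
- Voxel sizes travel in the manifest/CLI configuration, not in TIFF tags;
  tags are checked for consistency when present and the configured value
  wins with a warning on conflict.

## Known limitations

- The tracer assumes the tissue is the brightest structure below a mostly
  dark background; strong specular reflections at a coverslip would need a
  lateral crop (exposed via the profile span) or manual delineation.
- NSL depends on the lateral span over which the surface is delineated;
  the span convention is left to the user and should be held fixed within a
  study.
- The attached/detached distinction for outgrowths is made by the analyst
  (mask or ROI choice), not inferred automatically.
- The ImageJ `.roi` reader covers the classic int16 polyline/polygon layout
  only (no composite or sub-pixel ROIs).
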