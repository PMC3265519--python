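# Methods

This package implements the analysis chain of a stochastic optical
reconstruction microscopy (STORM) experiment on membrane-labeled neural
processes — from raw camera frames to a stitched, color-coded molecule
list and a resolution report — together with a forward simulator that
generates every input the chain consumes. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
data does and does not establish.

## Imaging model

**Spots.** A switching event of a photoswitchable reporter (e.g. Alexa 647
paired with an activator dye) is modeled as an elliptical Gaussian spot,
pixel-integrated (error-function differences per pixel edge, not
center-sampled), with total integrated signal equal to the event's photon
count. Widths are Gaussian standard deviations in nm throughout.

**Astigmatism.** A cylindrical lens encodes the axial position z in the
x/y width asymmetry. Both the simulator and the z lookup use the same
parameterization per axis,

    w(z) = w0 * sqrt(1 + u^2 + A u^3 + B u^4),   u = (z - c) / d,

with defaults w0 = 150 nm, |c| = 200 nm (wx and wy focal planes straddling
z = 0), d = 400 nm, A = B = 0, valid over z in [-400, +400] nm — the
window over which single molecules remain detectable. Sharing one
`CalibrationCurve` between forward model and analysis is deliberate: the
round-trip tests then isolate the estimator, not model mismatch. Building
a calibration from a bead z-scan fits this same form per axis by
least squares and refuses curves whose width difference wx - wy is not
strictly monotonic (the z lookup would not be invertible).

**Camera.** Poisson shot noise on signal + background (default
10 photons/px/frame), additive Gaussian read noise (sigma 2 counts),
constant offset (100 counts), unit gain. EM-gain excess noise is omitted;
it would scale all precisions by ~sqrt(2) without changing any of the
estimator properties tested here.

**Blinking.** One label is one antibody at one fixed position. Each label
emits `mean_localizations_per_label` events over the movie (default n = 4,
the same divisor the density calculus uses), placed in the imaging frame
immediately after its channel's activation frames; per-cycle activation is
Bernoulli with probability derived from that mean. Nonspecific
(imaging-laser) activations occur uniformly over imaging frames at a
per-frame rate; wrong-laser activations at a per-cycle rate per
(activating channel, victim channel) pair. Photon counts per event default
to a constant 5000 (an exponential option exists); dark-state kinetics and
bleaching are out of scope.

**Structures.** Labels are placed by a Poisson point process on the
*membrane surface* (2*pi*r*L for a tube of radius r, default 75 nm —
membrane labeling is what makes the high label density of thin processes
possible). Junction structures place a second tube rotated in-plane and
offset axially by `z_separation`.

## Localization

Per frame: difference-of-Gaussians band-pass (sigmas 1 and 4 px);
threshold at k = 5 times the robust (MAD) noise sigma of the filtered
frame — scale-free across brightness levels, since no absolute threshold
is defensible across simulated conditions; strict 8-neighborhood maxima;
7x7 px fit windows (covering ±3 sigma of the in-focus spot at 160 nm
pixels). Candidates whose windows overlap are *both* dropped: the fitter
assumes isolated single-molecule images, and a bright neighbor biases
both fits. Every rejection is counted by reason (overlap, border,
non-convergence, no signal, ellipticity gate, off-curve z).

Fits are least squares (`scipy.optimize.least_squares`) of the
pixel-integrated Gaussian plus constant background; symmetric width in 2D
mode, independent axis-aligned widths in 3D mode. Widths outside
[0.3x, 3x] of the calibration's width range are rejected. z is assigned by
minimizing the distance between (sqrt(wx), sqrt(wy)) and the calibration
curve in sqrt-width space — the conventional metric for this calibration
style — on a 1 nm grid with 3-point quadratic refinement; pairs farther
than a gate (default 1.0 sqrt-nm) from the curve are rejected.
Grid-search oracles in the test suite confirm the optimizer lands on the
global least-squares optimum of 16x16 fixtures to within 0.01 px.

## Drift, color, crosstalk

**Drift** is estimated image-wise: localizations are binned in time
(default 500–1000 frames/bin), each bin rendered as a 25 nm histogram,
lightly smoothed, and cross-correlated against the first bin's render;
the correlation peak is refined by per-axis quadratic interpolation.
Offsets interpolate piecewise-linearly between bin centers with constant
extrapolation at the ends; the reference bin is pinned at (0, 0). Axial
drift is assumed handled by the microscope's focus lock; the trace carries
a dz slot that defaults to zero.

**Color coding** is purely temporal: a localization in the first imaging
frame after a channel's activation block gets that channel; every other
frame is "nonspecific".

**Crosstalk.** Assuming the nonspecific activation probability is constant
across frames, the rate measured in imaging frames that do not follow an
activation pulse predicts the false count hiding in each channel's
post-activation ("apparent specific") count; actual specific = apparent
minus that expectation, floored at zero. The correction removes the
expected false count by seeded uniform thinning of the channel's
localizations (stochastic rounding keeps it unbiased over seeds). Uniform
thinning corrects channel *counts* — it cannot identify which individual
localization is false — so residual crosstalk is defined and measured as
the wrong-channel/right-channel apparent count ratio in a single-labeled
simulation; the correction takes an injected ~25 % ratio to below 5 %.
Wrong-laser crosstalk between designated channel pairs adds a configurable
expected count to the removal.

## Mosaic

Focal planes within a field of view are aligned in x/y by 2D-render
cross-correlation against the middle plane, then in z by correlating the
overlapping axial slabs of 3D renders (25 nm x/y, 50 nm z pixels; the
300 nm focal step is well inside the ±400 nm detection range, so adjacent
planes share structure). Adjacent fields of view are aligned on their
overlap regions the same way. Two numerical points matter for thin,
nearly-1D structures: both tiles are rendered over the strict common
bounding box (different window extents otherwise pull the peak toward
window-center alignment), and smoothing is kept light (sigma 0.5 px) so
the label speckle — not the tube envelope — pins the correlation along
the tube axis; the peak search is bounded by the stage repeatability
(300 nm default). Overlaps whose correlation prominence falls below a
confidence floor are flagged for manual override, never silently aligned.

The pairwise-offset graph is solved by equal-weight iterative relaxation:
each field moves to the mean of (neighbor position − pairwise offset),
one anchor fixed, until the largest per-iteration movement is below 1 nm
(cap 10 000 iterations). This is Jacobi iteration on the graph-Laplacian
normal equations, so on a connected graph it converges to the least-squares
layout — the test suite checks agreement with a direct normal-equations
solve on random graphs, and zero residual on consistent ones.
Manual offsets are honored as hard constraints by locking their fields
into rigid clusters before relaxation.

## Rendering and the resolution calculus

Rendering sums unit-volume Gaussians, one per localization, so total
intensity equals localization count (0.5 % border-truncation allowance).
The per-localization width defaults to the first-order photon-limited
estimate sigma = sigma_PSF / sqrt(photons) (background term omitted; this
affects display only). 3D renders bin z into 100 nm slices.

Localization precision is the FWHM of the pooled scatter of
isolated-emitter clusters, each recentered to its centroid, with a
Gaussian fit to the pooled histogram (not raw half-crossings). Label
density is localization count / region measure / n, with n = 4 events per
label; for d = 2 the data is projected. The Nyquist criterion sets the
sampling-limited resolution to twice the mean label spacing,

    alpha_Nyquist = 2 / a^(1/d)    (a in labels/um^d; 2000 / a^(1/d) in nm),

and the reported resolution combines it with the localization precision in
quadrature: resolution = sqrt(alpha^2 + precision^2). At the membrane
labeling density a = 2500/um^2 this gives alpha = 40 nm and, with 18 nm
lateral precision, a combined 2D resolution of 43.9 ≈ 44 nm; at the
cytoplasmic density 680/um^2, alpha = 76.7 nm. The density fold change
2500/680 = 3.68 maps to Nyquist-resolution folds of 1.92 (2D) and 1.54
(3D). A serial-scan comparison (voxels at a given pitch times dwell time)
puts a 20 x 20 x 0.5 um volume at 50 nm voxels and 10 us dwell at 16 s.

## Problem sizes and what the tests show

The in-silico experiments (`smlm.experiments`) use a 1 um tube segment at
the two labeling-density regimes, activation kept sparse (~0.1 expected events per
cycle) so the non-overlap assumption holds, and movies long enough for
every label's n = 4 events (50k–190k frames of a small 16x24 px field) —
a few minutes each on one CPU. End-to-end density recovery is compared
against the *realized* Poisson label density of the generated structure:
at a few hundred labels the realization itself fluctuates by several
percent, which is sampling noise of the ground truth, not pipeline error.
Recovered combined resolution agrees with the closed form within ~5 %,
dominated by the ~7–9 % of events lost to overlap/border/z-gate
rejections (entering the resolution at half weight through the square
root).

Because the simulator shares its PSF and noise models with the analysis
assumptions, these tests establish estimator correctness — unbiased
fitting, correct bookkeeping, correct calculus — not robustness to real
optical aberrations, sCMOS-style structured noise, dye photophysics
beyond the Bernoulli/uniform blinking model, or dense-emitter overlap.
Experimentally measured quantities that depend on microscope data
(18/50 nm precisions, measured FWHM profiles, exact residual crosstalk
percentages) are microscope properties, not reproducible from synthetic
data; the package instead verifies the corresponding *procedures* by
parameter recovery.

## Degenerate inputs and tie-breaks

Zero label density yields empty sets that flow through the whole chain;
flat ROIs and all-zero profiles are rejected with explicit reasons;
symmetric (astigmatism-free) calibrations refuse to build; disconnected
offset graphs list their components; drift bins below ~1000 localizations
warn; correlation peaks at array borders skip quadratic refinement on the
clipped side. Peak merging keeps the brighter candidate; equal-intensity
ties resolve by scan order (row-major).
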