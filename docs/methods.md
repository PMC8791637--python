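# Methods

This note documents the models and numerical choices behind `phaseq`, the
assumptions each one makes, and what a green test does and does not
establish.

## PSF model and the small-object intensity correction

The microscope PSF is modelled as an isotropic 2D Gaussian. Its FWHM is
estimated per channel from sub-resolution beads: for each bead the
brightest z-plane is selected (ties break to the lower index), a
horizontal linescan through the centre is fit with a four-parameter
Gaussian (amplitude, centre, σ, baseline), and FWHM = 2√(2 ln 2)·σ is
averaged over beads. Beads whose fit fails are dropped with a warning.
Averaging a vertical scan as well is available behind
`measure_fwhm(average_axes=True)`; the default is the horizontal scan
only.

Blur dilutes the measured mean of a bright object on a dark background.
The correction curve is built by rendering discs of diameters 1–50 px at
intensity 255 on a zero background, convolving with the unit-sum Gaussian
kernel (support truncated at ±4σ, renormalized; truncation error < 1e−4
of total mass), masking each convolved disc with Otsu's threshold, and
recording the factor 255/mean against the measured (equivalent-area)
diameter of the mask. A one-phase exponential association
`f(d) = plateau + (f0 − plateau)·e^(−k·d)` is fit to these points.

Two numerical choices matter here:

- **Sub-resolution points are excluded from the fit.** Below roughly
  2× FWHM the measured diameter is set by the PSF, not the object: discs
  of different true size collapse onto the same measured diameter with
  correction factors diverging to ~70, so factor-vs-measured-diameter is
  not single-valued there. Fitting through those points drags the plateau
  to ~0.89 and produces 20–30% error in the region where the correction
  is actually applied (d ≥ 12 px). The fit therefore uses only points
  with measured diameter ≥ 2× kernel FWHM (they remain visible in
  `sample_points`), with relative-error weighting and the plateau bounded
  to [0.9, 1.1]. Residual fit error in the applied region is ~2% for
  FWHM 2–5 px.
- **Disc rasterization is anti-aliased** (fractional pixel coverage at
  the rim), shared between the calibration and the synthetic generators
  so both sides mean the same thing by "diameter". A consequence: even an
  unblurred disc measures a correction factor slightly above 1 at small
  diameters (rim pixels partially covered), ~1.03–1.05 at d = 12–15 px.

## Partition coefficients

Droplets are segmented by a global Otsu threshold on a reference channel
(configurable; the brightest, most-enriched channel should be used).
Components are labelled in centroid (y, x) order. The bulk is the mean
intensity outside the union of all droplets dilated by 5 px (default;
clears the blur halo at FWHM 2–5 px). PC = corrected droplet mean / bulk
mean, per channel. Droplets with measured equivalent diameter < 12 px are
recorded but flagged `discarded` and excluded from every summary; the
floor is measured on the mask channel and shared by all channels.

**When the PSF correction is applied.** The calibration factor is
measured on discs over a *zero* background, but a droplet's measured mean
includes bulk signal blurred into the mask. Multiplying the whole mean by
`f(d)` therefore over-corrects by roughly `ε·f` in PC units (ε = the
blur-mixing fraction) — harmless at high PC, but it turns a PC = 1
channel (no blur bias at all: blur mixes equals) into PC ≈ 1.12. The
pipeline consequently applies the correction per channel only when the
raw mean actually increases with diameter (one-sided Spearman trend test,
α = 0.05, ≥ 5 droplets) — the signature of blur dilution. Always-correct
is available via `trend_pretest=False`. The residual over-correction for
enriched channels is the few-percent overshoot visible in recovery tests
(e.g. mean PC 3.14 at truth 3.0); it is a property of the method, not of
the implementation.

Flat-field correction divides by `(dye − dark)/max(dye − dark)`; the
field is clipped below at 1e−3 to guard division (clipped pixels are
logged). Background frames are subtracted per channel (the per-channel
assumption is documented in `core_io`; a shared frame can simply be
passed to every channel). Cluster densities convert per-field counts
(same segmentation, same minimum-size floor unless overridden) to
clusters/mm² using the full field area; enrichment divides per-cluster
means by the mean of the unclustered region outside the dilated cluster
union.

## FRAP analysis

Normalization follows
`N(t) = (I(t) − I_post)/(I_pre − I_post)` after background subtraction
and multiplicative photobleach correction (ROI divided frame-wise by the
reference region rescaled to its own prebleach mean). `I_pre` is the mean
of the prebleach frames (≥ 3), `I_post` the corrected ROI at the first
post-bleach frame, so N(0) = 0 and the prebleach mean is exactly 1.

Fits use `scipy.optimize.curve_fit` with deterministic multi-starts: the
rate guess comes from the time to half the final observed recovery and is
expanded into a fixed multiplicative grid; the biexponential start list
includes the nested (single-equivalent) start so the richer model never
ends up worse than the simpler one. Bounds: plateau ∈ [0, 1.2] (tolerates
noise overshoot), k ∈ [1e−4, 10] s⁻¹ (spans half-times from 0.07 s to
~2 h). Components are reported fast-first; fractions are absolute
(they sum to the plateau).

The plateau is flagged unresolved (`plateau_resolved = False`, the "nd"
case in tabular output) when the slowest fitted t½ exceeds half the
observation window or the Wald 95% interval for the plateau is wider than
0.3. The Wald (covariance-based) interval replaces a profile-likelihood
interval for cost; for these well-conditioned exponential fits the two
agree to the precision that matters for a binary flag.

Model selection uses the extra sum-of-squares F test,
`F = ((SS₁ − SS₂)/(dof₁ − dof₂))/(SS₂/dof₂)`, p from F(dof₁ − dof₂, dof₂),
choosing the biexponential iff p < α (default 0.05). **Known
limitation:** for this nested pair the test is only approximate — under a
single-exponential truth the extra parameters (second rate, split
fraction) are unidentifiable, and the empirical type-I rate on clean
simulations is ~1–2%, not the nominal 5% (conservative: fewer spurious
biexponential claims). Conversely, applying the test to traces averaged
*after* normalization inflates the rate (~13%), because dividing by a
noisy reference and anchoring N(0) to a noisy frame correlates residuals.
Power is excellent where it matters: with rates separated 20-fold the
biexponential is selected in ~100% of runs.

The bilayer-fluidity QC gate passes iff the single-exponential t½ is
strictly below 10 s.

## Adhesion morphometrics

`count_adhesions` reproduces the printed operator chain with its stated
parameters: rolling-ball background subtraction (radius 50), CLAHE
(block 19, 256 bins, max slope 6 — mapped to a scikit-image clip limit of
slope/bins), an exponential remap `v → M(e^(c·v/M) − 1)/(e^c − 1)` with
curvature c = 8 ln 2 (compresses the lower half-range ≥ 4×; counts are
robust to c within [3, 8]), a linear contrast stretch saturating 0.35% of
pixels, a σ = 2 Laplacian-of-Gaussian (sign-flipped so blobs are maxima,
negative side lobes clipped at zero, and the truncated kernel's constant
bias removed so a flat image maps to exactly zero response), the
"Default dark" threshold (ImageJ-style iterative intermeans on a 256-bin
histogram, foreground above threshold), and 8-connected particle analysis
with size 5–1000 px² and circularity 0.00–1.00 (circularity
4π·area/perimeter², clipped to 1).

The chain first rescales the field to a 0–255 float working range, which
both mimics the 8-bit display semantics the ImageJ operators assume and
makes the count exactly invariant under global gain.

Two guards stand in for the workflow's human steps. The global threshold
is degenerate on fields without real puncta — contrast normalization
manufactures full-range foreground from noise or from the cell-edge
gradient — so (1) an optional `roi_mask` restricts counting to the cell
interior (the role of hand-outlining), and (2) a confirmation filter
keeps only components whose mean intensity in the *original* image is at
least 1.5× their surrounding annulus, an automated surrogate for
"the final mask was compared to the original image". Both leave counts of
genuine high-contrast puncta untouched (80/80 recovered at noise up to
10% of contrast) while returning 0 on empty cells.

`total_adhesion_area` counts pixels in the fixed 16-bit window
[5500, 65535] and converts by the pixel area. The adhesion partition
coefficient automates the manual two-step thresholding with a three-class
multi-Otsu (background | cytoplasm | adhesion); a 2-px halo around
adhesions is excluded from the cytoplasm class (blur-contaminated pixels
a human would avoid), and PC = (mean_adh − bg)/(mean_cyto − bg) with the
background measured off-cell by the caller. This automated surrogate is
accurate to ~7% on resolved (≥ ~100 px²) adhesions; on near-PSF-scale
puncta the mask mean is intrinsically diluted by blur (the same physics
the droplet correction addresses) and the measurement reads low. GFP
gating keeps cells with background-subtracted mean GFP in [1000, 5000]
a.u., bounds inclusive.

## Synthetic data

The generators emulate: bead z-stacks (3D Gaussians, brightest at a
configurable focal plane, no overlap), droplet/cluster fields (anti-
aliased discs on a uniform bulk, Gaussian blur, multiplicative shading in
(0, 1], additive offset, Poisson shot noise on the pre-offset signal and
Gaussian read noise after), FRAP traces (one or two recovering fractions
with fast-first rates, configurable bleach depth and whole-field
acquisition bleaching, reference and background series), single-cell
adhesion images (elliptical puncta with sampled areas and aspect ratios
1–2, three intensity levels, mild optical blur), and dye/dark flat-field
pairs. Everything is deterministic given (parameters, seed).

Defaults encode the acquisition designs the measurements were built for:
FRAP at 1 s intervals for 90 s with 3 prebleach frames and ≥ 8 averaged
replicates; 20 beads per channel; droplet diameters 12–50 px at FWHM
2–5 px; adhesion puncta of 8–60 px² at ≥ 3× contrast with noise up to 10%
of contrast. Noise magnitudes (camera offset 40, read noise a few counts
at signal ~100–300, adhesion read noise ≤ 600 at contrast 6000) are free
parameters chosen to represent a well-exposed EM-CCD acquisition; they
are stated in config/defaults rather than fitted to any dataset.

What the generators do *not* emulate: droplet fusion and coarsening,
bilayer diffusion physics, sub-cellular structure other than puncta,
depth-dependent aberrations, or detector fixed-pattern noise. A green
recovery test therefore establishes that the estimators are unbiased and
stable for well-formed images of the stated statistics — not that they
are robust to every real-world artefact.

## Degenerate inputs and tie-breaks

Blank (zero-variance) images segment to an empty mask (logged, not an
error); a dilation that swallows the whole field, an empty cytoplasm
class, or a reference region at background level raise typed errors.
Focus-plane ties break low; component labels order by centroid;
background subtraction clips at zero; intensities are float64 from the
first correction stage onward regardless of input bit depth.
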