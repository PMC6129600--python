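# Methods

## Problem and pipeline

A toeless plantar print is a binary raster: foreground where the foot
contacted the ink plate. Arch height expresses itself in two ways in such a
print: the *midfoot contact fraction* (large for flat feet) and the *shape
of the outline* (a deep medial indentation lengthens the boundary and
concentrates curvature). The package measures both:

1. threshold the scanned image, fill interior dropouts, drop speck
   components, trace the ordered boundary;
2. geometric descriptors (area, perimeter, circularity);
3. Gabor-wavelet orientation features (second moment, orientation entropy);
4. contour curvature and mean bending energy (MBE);
5. Arch Index (AI) by automated trisection, classified at 0.21/0.26;
6. Arch-Height Index (AHI), a linear model on perimeter and MBE, classified
   at 0.23/0.27 or at batch quartiles.

## Conventions and parameters

| parameter | default | meaning |
|---|---|---|
| `resolution_px_per_mm` | 2.0 | raster scale; the AHI coefficients assume it |
| `threshold`, `polarity` | 128, `light` | foreground = intensity ≥ threshold |
| `fill_holes` | on | contact regions are treated as solid |
| `min_component_frac` | 0.01 | components below 1% of foreground are specks; larger ones (split heel/forefoot of severe cavus prints) are kept and analysed as a union |
| `perimeter_estimator` | `boundary_count` | boundary-pixel count × π/4 |
| `curvature.sigma_px` | 2.5 | smoothing scale of the curvature field |
| `gabor.k0_mag` | π/4 rad/px | 8 px carrier wavelength (4 mm stripes) |
| `gabor.epsilon` | 4 | envelope anisotropy (std √ε along orientation) |
| `gabor.n_orientations` | 18 | 10° orientation bins on [0, π) |
| `gabor.mag_floor` | 0.1 | histogram magnitude floor (fraction of peak) |

Coordinates are (row, col), origin top-left. Boundary membership uses
4-connectivity (a foreground pixel with a background 4-neighbour); tracing
order uses the Moore 8-neighbourhood and is normalized to positive signed
polygon area. Perimeter and area sum over components.

## The arch measures

**Arch Index.** The clinical construction projects the print onto a line
from mid-heel to the second toe; with toeless prints that landmark does not
exist, so the longitudinal axis is the major principal axis of the
foreground pixel distribution. The projected extent of the foreground is
cut into three equal intervals; AI is the midfoot pixel fraction. Pixels on
a cut line go to the lower-index section (deterministic tie-break). The
principal axis makes AI rotation-invariant (tested to within 0.01 at 37°);
heel/forefoot polarity — irrelevant for AI, used only for reporting — is
decided by transverse spread at the two ends (the narrower end is the
heel; the forefoot of a print is anatomically the wider end).

**Arch-Height Index.** AHI = β_P·P + β_MBE·MBE + β₀ with the fitted values
β_P = −7.351·10⁻⁵ px⁻¹, β_MBE = −1050.964 px², β₀ = 0.4597. Both slopes
are negative: longer and more strongly bent outlines (deep arches) score
lower. The score mimics the AI scale, with mean ≈ 0.25 and SD ≈ 0.025 over
a screening sample; the 0.23/0.27 cut-offs are the quartiles of that
distribution (Q1/Q3 of Normal(0.25, 0.025) sit at μ ± 0.6745σ = 0.2331 /
0.2669). `derive_quartile_cutoffs` re-derives cut-offs from any score
batch using linear-interpolation quantiles; boundary classification is
inclusive on both sides, mirroring the Arch Index convention. An OLS refit
(`fit_ahi_model`) is provided to recalibrate the coefficients for data
acquired at other scales or tracing conventions.

## Numerical choices

**Curvature.** The level-set expansion
k = (f_xx f_y² − 2 f_x f_y f_xy + f_yy f_x²)/(f_x²+f_y²)^{3/2} is evaluated
on the Gaussian-smoothed mask, with partial derivatives by
Gaussian-derivative filters at the same scale (effective smoothing √2·σ).
Gradient magnitudes below 10⁻⁶ zero the field; the sign is fixed so convex
boundaries are positive. Sampling the field at integer contour pixels
retains staircase ripple of the rasterized edge, which inflates squared
curvature; each contour pixel is therefore projected onto the f = ½ level
set (two Newton steps along the gradient, capped at 1 px) and the field is
sampled there by cubic interpolation. With σ = 2.5 px the disk oracles
agree with 1/r and 1/r² to a few percent (σ = 2 leaves ≈ 20% upward bias
in MBE on a radius-50 disk, which is why the default is 2.5). The MBE
scale law (∝ s⁻²) holds when the measurement scale σ is held fixed
*relative to the shape*; comparing resolutions therefore scales σ with
the raster.

**Gabor bank.** Kernels are mean-corrected (complex mean subtracted) so
flat regions respond ≈ 0; convolution is frequency-domain with
edge-replicated padding, so a constant image responds ≈ 0 everywhere
including the canvas border. Per pixel the bank keeps max |response| and
the argmax orientation; the orientation histogram bins by filter index
(guarding the exact-edge round-off of θ_k = kπ/K) over foreground pixels
above the magnitude floor. The second moment is the raw (non-central)
mean of squared magnitude over the foreground — the central-moment and
full-frame alternatives were considered and rejected as less directly
tied to the print's oriented structure. Entropy uses natural logarithm
with 0·ln 0 = 0. At orientation-ambiguous pixels (corners, symmetric
edges) the argmax may resolve either way between tied orientations;
orientation-field tests therefore assert on the 95% of well-defined
pixels.

**Perimeter.** The default ×π/4 boundary-count convention is what the AHI
coefficients were calibrated with and is kept for score fidelity, although
it is not a consistent length estimator. The chain-code estimator
(1 axial, √2 diagonal) is consistent up to the classical digitization
bias: on a digitized circle it overestimates arc length by ≈ 5%, so
chain-code circularity of a disk lands ≈ 10% above 4π rather than the
few-percent agreement a corrected estimator (e.g. Vossepoel–Smeulders
weights) would give. The plain estimator is kept deliberately — both
conventions are exposed, and the bias is asserted in the tests.

## Synthetic footprints

The generator emulates a toeless pedograph print: the convex hull of a
heel disk (radius 0.3·width) and a forefoot ellipse (semi-axes width/2 ×
0.17·length) forms a smooth flat-foot blob; an ellipse "bite" subtracted
at the medial midfoot creates the arch, with penetration arch_depth ×
(0.92 of the midfoot width), so depth ≈ 1 narrows the band below 10% of
foot width and finally disconnects heel from forefoot. A 3 mm Gaussian
rounding pass removes rasterization corners (real ink outlines have
none); both the bite and the rounding are inclusion-monotone, so midfoot
area decreases monotonically with arch depth. Optional boundary noise
radially perturbs the traced outline (contour-smoothed Gaussian offsets)
and re-rasterizes. Defaults (length 180 mm, width 90 mm, 2 px/mm) give
flat prints with MBE ≈ 1.2·10⁻⁴ px⁻² and AHI ≈ 0.25–0.28, rising to
≈ 4.5·10⁻⁴ px⁻² for deep arches — the regime the fitted model's
coefficients imply — and an AI sweep spanning both clinical cut-offs.

What the generator does *not* emulate: toe remnants, partial heel strike,
pressure-dependent ink density (prints are strictly binary), bony
prominences, or the population covariance between foot length, width and
arch height. Passing tests therefore demonstrate correctness of the
measurement pipeline and the qualitative arch-height response, not
clinical accuracy on real pedographs.

## Problem sizes

Tests and validation run on disks of radius 25–80 px, gratings of ~100 px,
and synthetic prints of ≈ 400×220 px; batch statistics (quartile
derivation, label recovery) use 60 prints and 10⁴ Monte-Carlo score draws;
OLS recovery uses n = 200. These sizes keep every oracle's discretization
error well below the asserted tolerances.

## Known limitations

* The heel/forefoot polarity heuristic can flip on atypical shapes; it
  does not affect AI or AHI.
* The ×π/4 perimeter convention underestimates true boundary length; AHI
  scores computed with the chain-code estimator are *not* comparable to
  the published coefficients.
* Multi-component prints concatenate contours for MBE and sum P and A;
  orientation features are computed over the union mask.
* The AHI coefficients assume the 2 px/mm reference scale; use
  `fit_ahi_model` to recalibrate at other resolutions.
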