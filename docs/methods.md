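# Methods

This note documents the models behind `coda`, the parameters that matter,
the numerical choices, and the limitations a user should know before
trusting results on real data.

## Imaging model

A short laser pulse deposits an initial acoustic pressure `p0(x, y)`
proportional to local optical absorption. The pressure propagates at a
constant sound speed `c0` through a homogeneous, lossless medium and is
recorded by an ultrasonic transducer that circles the object (circular-scan
photoacoustic computed tomography). All modelling is two-dimensional: the
object is the imaging plane, and detectors are points or flat line segments
in that plane.

### Forward model

The pressure at a point receiver follows the 2D wave equation, whose
cylindrical Green's function gives

    p(r0, t)  ∝  ∂/∂t ∫∫_{|r−r0|<c0 t}  p0(r) / sqrt(c0²t² − |r−r0|²)  dA,

a sharp wavefront followed by a decaying tail. The integral kernel is
shift-invariant in the squared variables `(c0²t², d²)`, so the package
evaluates it by binning pixel weights over `d²` and convolving with the
bin-averaged `1/sqrt` kernel — exact arrival times and superposition at
`O(N_pixels)` cost per detector, orders of magnitude cheaper than a
full-wave solver. Waveform-level equality with a grid-based wave simulation
is not claimed. The tail matters: without it (i.e. with a pure impulse
shell response) the universal back-projection formula hollows out every
extended absorber.

Two discretization details:

* arrivals are linearly splatted between adjacent bins, and the resulting
  series is convolved with a triangular kernel of half-width
  `2·pitch/(c0·dt)` — a pixel is a patch, not a point, and without the
  footprint kernel the Cartesian raster aliases the wavefront into
  broadband noise on extended objects;
* the time window must cover the farthest grid pixel; a too-short window
  raises an error naming the required sample count.

### Finite aperture

A flat detector element of diameter `a` lying tangent to the scan circle is
modelled as the mean of point receivers spaced every 0.2 mm along the
element (2 mm → 11, 10 mm → 51 sub-elements; 0.2 mm is well below the
0.6 mm wavelength at 2.5 MHz). This reproduces the tangential path-length
spread that causes "spinning" lateral blur: signals from off-center sources
smear in time, and back-projection elongates those sources tangentially,
the more so the larger the aperture and the farther the source from the
scan center. Element directivity beyond geometric path-difference averaging
is not modelled.

### Receive response

The transducer response is a zero-phase Gaussian-magnitude band-pass with
the stated center frequency and −6 dB fractional bandwidth (defaults
2.5 MHz, 75%). By default the response also keeps a baseband shelf
(gain 0.9, flat below the resonance, following the upper Gaussian skirt
above it). A strict band-pass has gain ≈ 0.007 at DC and removes the slow
shell-integral components that carry the interiors of extended absorbers;
reconstructed PACT images of such objects visibly retain their interiors,
so the default keeps the baseband. `baseband_gain=0` restores the strict
band-pass.

### Noise

"40 dB SNR" means additive white Gaussian noise with variance
`mean(signal²)/10⁴`, computed over the whole filtered sinogram, added after
the receive filter. The achieved SNR is reproducible per seed and measures
back to the nominal value within ±0.5 dB.

## Universal back-projection

Each detector contributes `b(r0, t) = 2 p − 2 t ∂p/∂t` evaluated at the
time of flight `t = |r0 − r|/c0` (linear interpolation in time;
out-of-window times contribute zero and are counted in the log). For the
full equiangular ring the contributions are averaged uniformly; an exact
per-pixel solid-angle weighting (`weighting="solid_angle"`) is available
for uneven coverage. The output is signed: the negative rims flanking
strong absorbers are preserved deliberately, because they are the input the
correction stage removes.

On a 2D circular scan this formula is not an exact inverse: it underweights
low radial frequencies, so large uniform disks reconstruct with interiors
at roughly half their rim amplitude. This is the main known accuracy limit
of the package (see Limitations).

## Adaptive projection-domain correction (ABP)

Steps, given a back-projected image normalized to its peak:

1. **Segmentation.** A single global Otsu threshold splits the image into
   target (values above threshold) and background (everything else,
   including all negative values — artifacts by definition). The threshold
   is computed in log-intensity over three decades below the peak, because
   a linear-histogram Otsu lands inside the target amplitude range on
   high-dynamic-range BP images and cuts off dim structures
   (`segmentation="otsu-linear"` restores the linear variant).
2. **Radon transforms.** Both parts are transformed over θ ∈ [0°, 180°) at
   1° steps, ρ sampled at the pixel pitch (scikit-image `radon`, physical
   units). The target's shadow interval `[m_θ, n_θ]` per angle is the
   outermost pair of bins exceeding 10⁻³ of the global maximum (one
   interval per angle — the convex hull of the shadow).
3. **Background interpolation.** Inside each `[m_θ, n_θ]` the full
   projection is replaced by the straight line through its endpoint values;
   outside, it is untouched. This deletes the negative rims and the
   rotational clutter that the target itself casts into its own shadow.
4. **Adaptive attenuation.** The target projection is scaled by
   `K · w(α)/w_max` with the tangent weight
   `w(α) = tan( R_T(α)/R_max · (π/2 − k) )`, `R_max` and `w_max` taken over
   the angle's shadow interval. `w` is strictly increasing in the
   projection value for `k < π/2`, so stronger projections keep
   proportionally more weight and the target's hierarchy survives.
   Defaults: `K = 0.35` (center of the optimal contrast range 0.2–0.5),
   `k = π/4` (midpoint of (0, π/2], making `w ∈ [0, 1]`). Whether the
   weight argument is the target-only or the full projection is ambiguous
   in principle; target-only is the default (`weight_on="full"` switches).
5. **Reconstruction.** The corrected projections
   `R_A = K (w/w_max) R_T + R_L` are inverted and the result is rescaled
   back to the input's amplitude.

### Numerical evaluation of step 5

A literal filtered back-projection of `R_A` followed by a global rescale is
available (`rescale="global"`), but it is poorly conditioned in two ways.
First, the discrete Radon round trip costs 20–30% relative error on sharp
images, paid by all retained content. Second, the global rescale undoes the
uniform attenuation `K·c̄` of the target (where `c̄` is the target-mass-
weighted mean of `w/w_max`) by multiplying the whole image, which amplifies
every background residual by `1/(K·c̄)` ≈ 4 — re-introducing the artifacts
the correction just removed and inverting the method's benefit.

The default path therefore evaluates the same operator in split form:

* the patched background `R_L` reconstructs by FBP (ramp filter; it is
  smooth, so the inversion is accurate);
* the attenuated target inverts through the exact identity
  `iradon(c·R(x)) = c·x` for its uniform part — the rescale then cancels
  `K·c̄` analytically, touching nothing else — while the remaining
  angle-dependent modulation is applied as a per-pixel weight field
  `ŵ(x)`, the ratio of unfiltered back-projections of `(w/w_max)·R_T` and
  `R_T`. The ratio is non-negative and ring-free, and reduces to the exact
  inverse when the weights are angle-independent.

The corrected image is defined on the inscribed circular field of view;
the corners beyond it are only extrapolated by 180° projections and lie
outside the imaged area, and are set to zero. One consequence of the
component-wise rescale: the final image is invariant to `K` (the constant
still scales the corrected projections returned by `correct_projection`,
and acts fully in the `rescale="global"` path).

**CODA** = acquiring with the small (2 mm, damped) aperture *and* applying
this correction.

## Evaluation

PSNR and SSIM are computed after clipping the signed reconstruction at zero
(negative values are artifacts, and the ground truth is non-negative) and
max-normalizing both images. SSIM uses a 7-pixel window and unit dynamic
range. Line profiles are bilinear samples along a physical segment; FWHM
interpolates the half-max crossings linearly; the edge MTF is the
normalized magnitude spectrum of the derivative of a monotone edge profile.

## Synthetic phantoms

* `points` — five binary 0.5 mm disks: one at the scan center, four at
  10 mm along the axes, probing the spatially variant lateral blur.
* `vessel` — a seeded procedural binary vessel: a smooth spline trunk
  crossing the field with tapering width and three branches rooted on it
  (single connected component, reproducible per seed). Only the
  topological character — elongated, branched, sub-millimetre widths —
  matters to the method; any binary image can be substituted.
* `spheres` — eight disks, diameters 10…3 mm, initial pressures 0.1…0.8
  (largest = faintest), centers on a 14 mm ring, non-overlap enforced;
  probes amplitude fidelity across an 8:1 dynamic range.

All phantoms live on a 50 × 50 mm grid and stay clear of a 2 mm absorbing
boundary margin. Disk rasterization is binary (pixel center inside the
radius), keeping binary phantoms exactly binary.

The generators emulate the geometry of targets, not tissue: no optical
fluence, no acoustic heterogeneity or attenuation, no out-of-plane
structure. Passing tests therefore demonstrate the reconstruction and
correction machinery under the stated acquisition model, not performance
on real tissue data.

## Study protocol and problem sizes

The simulation study runs 360 detector positions on a 23 mm ring, apertures
{10, 6, 2} mm, 2.5 MHz / 75% response, 2226 samples at 21 ns, 1500 m/s,
40 dB noise. Evaluation uses a 250 × 250 grid at 0.2 mm pitch (the imaged
area at reduced sampling) — the package's standard reduced scale, at which
a full five-method, three-phantom, three-seed study completes in about a
minute on one core. An experimental-bench preset (`lab`: 35 mm radius,
5 MHz / 79% bandwidth) ships for completeness.

## Known limitations

* The universal back-projection formula is used as published; on 2D
  circular-scan data it underweights low radial frequencies, so interiors
  of absorbers much larger than the acoustic wavelength reconstruct at
  roughly half the rim amplitude. This depresses PSNR for the graded-disk
  phantom (all methods saturate near 20 dB there) and slightly favours
  larger apertures on that phantom's PSNR; structural metrics are
  unaffected.
* The forward model is analytic 2D: no grid dispersion, no attenuation, no
  elevation effects, no electrical impulse-response phase.
* Segmentation is a single global threshold; heterogeneous absorption with
  targets below the threshold is out of scope (locally adaptive
  multi-threshold segmentation would be the next step).
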