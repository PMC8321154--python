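# Methods

## The emulation model

An X-ray plenoptic camera records, in one exposure, a grid of pin-hole
images (PHIs) of the sample — one per viewing direction.  Geometrically such
a light-field is a limited-angle cone-beam acquisition: because attenuation
line integrals do not depend on the direction of propagation, the bundle of
rays that a camera collects can equally be produced by moving a point X-ray
source to a set of transverse positions `S(u,v)` in a plane and a detector
to matching positions `D(u,v)`, with every `S→D` line crossing the optical
axis at the focal plane `z = z0` (source plane at `z = 0`, detector plane at
`z = zsd`).  `xlfemu` implements this mapping for the three apparatus
families and everything downstream of it: phantom synthesis, forward
projection, flat-field pre-processing, shift-and-add refocusing, two-cue
depth estimation and quantitative evaluation.

The three mappings (lengths mm; view indices `pu, pv` signed integers on an
odd grid):

* **Diffracting crystal** — PHI centers `P(u,v)` on the detector are inputs
  (they derive from the crystal's reciprocal lattice, outside scope);
  `D = P`, `S = −z0/(zsd−z0)·P`.  The crystal design uses a parallel beam;
  emulating it with a cone beam distorts size and depth unless
  `(zsd−z0) ≪ z0`, so a warning is raised when `(zsd−z0)/z0 > 0.2` (no
  correction is applied).
* **Poly-capillary** — the pin-hole mask pattern `H(u,v) = (pu·δu, pv·δv)`
  demagnified by the taper factor `t = a_out/a_in` gives `S = t·H`,
  `D = −(zsd−z0)/z0·t·H`.  Feasibility: beamlets separate only if
  `a_out` exceeds the beamlet waist `w = 2·z0·φ`, with
  `φ[mrad] ≈ 30/E[keV]` the total-reflection critical angle.
* **Decoding lenses** — PHI positions on the camera's main lens become
  source positions `S(u,v)`; `D = −(zsd−z0)/z0·S`.  The camera's spatial
  resolution is `δs = (MLA pitch)/|M|`, `|M| = z1/z0,cam`, its angular
  resolution `δu = (sensor pixel)/|m|`, `|m| = z2/z1`; the emulation's
  effective pixel is the scanner pitch divided by the cone-beam
  magnification `zsd/z0`.

Reference configuration (packaged in `presets`): 9×9 sources at 2 mm pitch,
`z0 = 890.725 mm`, `zsd = 1012.95 mm`, 128×128-pixel PHIs at 150 μm.  This
yields an angular range `atan(2·8/890.725) = 1.029°`, an effective pixel of
`150·z0/zsd = 131.90 μm` and a spatial magnification of ≈18.05 (nearest
integer 18) relative to the reference camera (`δs ≈ 7.309 μm`).  Note the
reference publication prints the effective pixel as ≃131.55 μm while the
stated formula with the stated distances gives 131.90 μm, a 0.3%
discrepancy; this package implements the formula.

## Depth of field and the depth-uncertainty bound

With ~1° of angular range, depth resolution is parallax-limited: a point
must move axially by `bound = effective_pixel / tan(angular range)` before
it shifts by one pixel between the extreme views.  For the reference
geometry `bound ≈ 7.34 mm`; twice the bound (≈14.69 mm) serves as the depth
of field (DoF) of refocused images — the depth resolution of a limited-angle
tomographic reconstruction with the same range.  A published figure of
15.05 mm DoF / 7.65 mm uncertainty for this geometry derives from a formula
in earlier work not reproduced here; the package exposes its own parallax
bound and treats the larger figure only as an upper bound.  Within one DoF
of the focal plane, sharpness carries essentially no depth information by
construction; only the correspondence cue (and, outside the DoF, defocus)
discriminates.

## Phantoms and ground truth

Phantoms are analytic primitive lists (spheres, capped cylinder segments,
each with a signed attenuation delta in mm⁻¹) plus a voxel grid
declaration; voxelization composes background + deltas with 2× supersampled
anti-aliasing and clips at zero.  Exact ray–primitive intersections provide
both the ground-truth depth map (per central-view pixel: the mean axial
coordinate of the centers of all *object* primitives on the line of sight —
background structures such as the gel container are excluded) and analytic
object footprints for evaluation, so detection error never contaminates
depth error.

* **Branch phantom** — a connected random tree of cylinder segments;
  thicknesses shrink from 1.2 mm at the root to 0.1 mm at the tips (at the
  reference camera scale, 66.66 μm down to 5.55 μm — arteriole to capillary
  calibre).  Segments stay within a slab of ±25 mm around z0.
* **Bubble phantom** — air bubbles (negative delta) in a gel cylinder
  (μ = 0.02 mm⁻¹, chosen so the 54 mm gel path transmits ≈34% and bubble
  contrast is a few × the counting noise at 10⁴ photons/pixel).  The
  container axis lies along the optical axis so bubble depths can span
  z0 ± 20 mm inside the ≈16.8 mm transverse field of view.  Radii span
  1–4 mm with a Beta(1,3) distribution skewed toward small bubbles, as in
  real gas-in-gel populations, and rejection sampling enforces both 3-D
  non-overlap and limited overlap of central-view projections: the
  per-bubble depth comparison the reference experiment performs presumes
  individually discernible bubbles, and unconstrained packings of 1–4 mm
  spheres in this field of view leave most footprints multiply occluded.
* **Crossing phantom** — two straight segments at different depths that
  overlap in projection; the fixture for the semi-transparency limitation.

The physical samples' depth extents are not published; defaults are chosen
so objects span several DoF units (depth recovery is nontrivial) rather
than to match any physical specimen.

## Forward projection and noise

Rays are cast from each view's source to every detector pixel center
(detector perpendicular to the axis; the panel translates, it does not
tilt).  The line integral uses uniform parametric sampling of the ray
segment clipped to the volume box, step ≤ voxel/2, trilinear interpolation
and trapezoidal accumulation; the single-ray entry point parametrizes the
segment in a canonical orientation, making the integral exactly
direction-independent (the property underlying the source/detector
exchange).  Against analytic sphere chords the integral is accurate to ~1% at voxel
= r/10 (alignment-dependent; ~0.25% at r/20), with grazing rays near the
rim excluded — there the chord varies faster with impact parameter than
any fixed voxelization resolves.  Counts follow `Poisson(I0·exp(−∫μ dl))`; open-beam
(flat) images receive the same noise treatment.  The focal spot is a point
and the detector has no PSF; both are deliberate idealizations.

## Pre-processing

Per-PHI open-beam normalization (raw/flat), conversion to absorbance
(−log T, making signal additive along rays), 21×21 uniform-box background
subtraction (removes the smooth container signal; applied in the bubble
pipeline only) and contrast inversion so bubbles carry positive signal.
With noisy data a per-pixel noise-variance map is propagated through the
chain by first-order error propagation (`var(−log(raw/flat)) ≈ 1/raw +
1/flat`, box subtraction scaling it by `1 − 1/441`); the depth estimator
uses it for noise calibration (below).  The foreground mask is Otsu's
threshold on the depth-summed focal stack followed by removal of connected
components smaller than 0.1% of the image — no particular segmentation
method is canonical here; Otsu is this package's (parameter-free, testable)
choice.

## Refocusing

Shift-and-add: the focal-plane point `q` at depth `z` maps, for the view
with source `S` and detector center `D`, to the detector position
`S + (q−S)·zsd/z`; each PHI is sampled there bilinearly and the views are
averaged, excluding views whose footprint does not cover the pixel.  At
`z = z0` the mapping aligns all views exactly.  The default depth sweep
covers `z0 ± 3·DoF` in steps of `DoF/4` (the published depth sampling is not
printed; this is the package's DoF-scaled default).

## Two-cue depth estimation

* **Defocus cue** — per depth, the windowed mean (11×11 by default) of the
  |5-point Laplacian| of
  the refocused image; best depth per pixel is the argmax.  With counting
  noise the sharpness of noise itself depends on depth — refocusing at z0
  resamples detector pixels exactly, while other planes interpolate and
  smooth the noise — so the raw response has a spurious bump at z0.  The
  package therefore refocuses a synthetic noise field with the data's
  propagated per-pixel variance through the identical pipeline and divides
  the data response by the noise response, cancelling that profile.
* **Correspondence cue** — per depth, the standard deviation across views of
  the per-view reprojections (pixels with <2 contributing views excluded),
  averaged over the same window; best depth is the argmin.  With noisy data
  the reprojected variance of a matching synthetic noise field is
  subtracted before the square root, isolating the parallax-induced
  deviation.  Both cues refine their extremum to sub-step precision with a
  parabolic fit through the extremum and its two neighbours.  The window
  size was chosen by validating full bubble runs on two independent seeds;
  it trades counting-noise suppression against mixing of neighbouring
  structures.
* **Confidence** — peak-to-mean ratio (defocus) or mean-to-min spread ratio
  (correspondence), squashed by `x/(1+x)`, then attenuated by
  `s²/(s²+s̄²)` where `s` is the response strength and `s̄` its spatial
  mean: ratio-based confidences are scale-invariant, so without the
  attenuation a textureless pixel whose response curve is pure residue can
  masquerade as confident.  Textureless pixels instead defer to the merge
  regularizer.  Both confidences are invariant under global intensity
  scaling of the light-field.
* **Ties** in argmax/argmin resolve toward the sample nearest z0 (stable,
  documented).

The cues are merged by minimizing

    Σ_p [ c_d(Z−Z_d)² + c_c(Z−Z_c)² ] + λ_grad‖∇Z‖₁ + λ_lap‖ΔZ‖₁

over depth maps `Z` (depth-step units; anisotropic ℓ1; forward-difference
gradient, 5-point Laplacian), with λ_grad = λ_lap = 0.1 by default.  The
solver is Chambolle–Pock with steps `τ = σ = 1/√72` (from the operator-norm
bound ‖∇‖² ≤ 8, ‖Δ‖² ≤ 64) and *monotone acceptance*: the reported iterate
is the best-objective primal iterate so far, so the logged objective is
non-increasing by construction while the underlying iteration is standard.
Initialization is the pointwise confidence-weighted cue average; nothing is
random.  The cue-specific confidence formulas and regularizer weights of
the original two-cue algorithm are not published; the ones here are this
package's documented choices, not claims of equivalence.

The estimator assumes one opaque object per line of sight.  Where two
semi-transparent objects overlap in the central view the estimate tends
toward an intermediate depth; this limitation is reproduced (and measured
by the crossing-branch pipeline), not fixed.

## What the synthetic data does and does not show

The generator emulates the reference scan geometrically and statistically
(point source grid, Beer–Lambert attenuation, Poisson counting noise,
per-view flats) but not: finite focal spot (20 μm in the physical scanner),
detector PSF, scatter, beam hardening, phase contrast, or capillary
vignetting (available only as an optional per-view weight).  Passing tests
therefore demonstrate the geometric and algorithmic correctness of the
pipeline under ideal-detector conditions, not end-to-end fidelity to any
physical acquisition; in particular the published real-data depth errors
(1.27 ± 0.94 mm) derive from a physical acquisition and are deliberately
not reproduction targets.

## Numerical choices and degenerate inputs

Transmission is floored at 1e−6 before logarithms; zero or negative flats
are an error naming the offending view.  Uniform light-fields and constant
focal stacks give zero confidence everywhere (guarded against float
residue by comparing responses to the data scale).  All-zero confidences
yield an all-invalid depth map rather than an error.  Depth values are
clipped to the focal-stack range.  Problem sizes in the packaged
experiments (128×128 PHIs, 81 views, 0.15 mm voxels, 25 depth samples, 300–
600 merge iterations) are chosen so a full bubble pipeline completes in a
few minutes on one CPU core while keeping voxel and depth sampling below
the relevant physical scales (bubble radius, DoF/4).
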