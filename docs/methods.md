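# Methods

This note records the models, conventions, parameter choices and known
limitations behind `limbus3d`, in the order data flows through the package.

## Coordinate frame and laterality

All surface analysis happens apex-centered: the corneal apex at the origin,
+Z toward the camera, the anterior surface stored with z ≤ 0 and analysed
as sag s(r) = −z, which grows from zero at the apex. Meridian angles are
degrees counter-clockwise from +X in the en-face view.

Clinical labels follow an *unmirrored* camera image of the face: for the
right eye the nose is toward +X, so nasal = 0° and temporal = 180°;
mirrored for the left eye; superior = 90° and inferior = 270° for both.
Tilt angles of the limbus best-fit plane z = ax + by + c are
θ_y = atan(a) (about the Y axis, counter-clockwise from +X in the XZ
plane) and θ_x = atan(b) (about the X axis, counter-clockwise from +Y).
Under this pairing a limbus that sits higher on the nasal side produces a
positive θ_y in right eyes and a negative θ_y in left eyes, and mirroring
a right eye to a left eye flips the sign of θ_y while preserving θ_x —
the asymmetry a bilateral cohort needs to express.

Apex-centering subtracts the device-reported apex coordinates and is
idempotent. A tilted eye legitimately rises slightly above the apex plane
(≈ R(1 − cos τ) ≈ 5 µm at τ = 2°), so validation allows z up to 0.05 mm
rather than demanding strict non-positivity. Laterality is never inferred:
a record without it fails loading.

## Synthetic surfaces: the ground-truth generator

The generator defines meridian profiles through the *second* radial
derivative and integrates twice:

    d2(r) = κ_c − A·exp(−(r − r_L)² / 2σ²),   s(0) = 0, s′(0) = 0,

with corneal base curvature κ_c = 1/7.8 mm⁻¹, dip amplitude A = 0.3 mm⁻¹
and dip width σ = 0.35 mm by default, integrated in closed form (error
functions), so s, ds/dr and d²s/dr² are all analytic. The Gaussian
curvature dip encodes the cornea-to-sclera transition, and — because the
base curvature is constant — the interior minimum of d2 falls *exactly* at
the ring radius r_L(θ), giving exact ground truth for the detector. A
`scleral_blend` variant adds realism by relaxing the base curvature toward
1/12 mm⁻¹ through a Gaussian-CDF blend centred on the ring; its analytic
d2 minimum is then displaced ≈ 0.02 mm from the centre, so truth for that
variant is defined at the blend centre and tests against it must budget
for the displacement (`analytic_d2_minimum` computes the displaced
argmin). A dip amplitude of zero leaves d2 without an interior minimum and
is rejected (`BadParameters`).

Surfaces are sampled on a 0.05 mm XY grid (or uniformly scattered points)
out to 9.5 mm, rotated rigidly by the truth tilts, optionally degraded
with i.i.d. Gaussian height noise, and optionally cut by eyelid occlusion
sectors. Tilt rotations are built as R = Rx(θ_x)·Ry(−atan(tan θ_y·cos θ_x)),
the exact inverse of the plane-fit convention, so fitting the analytic
ring recovers the requested angles to 1e-6°, cross-terms included. All
randomness flows through one seeded generator; the same seed reproduces
the same field bit-for-bit.

What the generator deliberately does **not** emulate: tear-film and
fluorescein artefacts, spatially correlated device noise, astigmatic or
keratoconic corneas, limbal width (the transition is a single ring), and a
non-planar "true" limbus beyond what per-angle ring radii express. Passing
the recovery tests therefore demonstrates correctness of the algorithmic
chain under the stated noise model, not clinical accuracy on pathological
eyes.

The matched image generator renders a pupil disc (radius 80 px) inside an
iris ellipse (295 × 287.5 px semi-axes) on a scleral background at
intensities (20, 110, 220), with two optional 255-level highlight dots
stacked vertically near the centre (the profilometer's illumination
spots), plus clipped Gaussian noise (sd 8). The analytic per-degree iris
ellipse radius is the WTW ground truth.

## Limbus detection

1. **Polar resampling.** The scattered surface is interpolated onto 360
   meridians × 0.01 mm radial steps by local linear (Delaunay)
   interpolation. A polar sample is *valid* only if the longest edge of
   its supporting triangle is ≤ 3× the median nearest-neighbour spacing of
   the cloud. This is what makes eyelid gaps honest: the long sliver
   triangles that span an occluded sector are flagged instead of silently
   bridged, so a 60° occlusion yields exactly that closed sector of
   invalid meridians while every other meridian's radius moves by < 1 µm.
2. **Derivatives.** Each contiguous valid run is fitted with
   Savitzky–Golay local cubics; d1 and d2 come from the fitted
   coefficients (exact on cubics, including at run ends via polynomial
   edge handling). Runs shorter than one window propagate as invalid;
   a meridian with no fittable run raises `WindowTooWide`, which the model
   converts to an invalid meridian.
3. **Turning point.** Within the search window 4.5–8.5 mm (bracketing all
   plausible limbal radii) the limbus radius is the most prominent
   interior local minimum of d2, ties broken toward smaller r (the
   corneal side, conservative against scleral artefacts), subject to a
   prominence floor of 0.05 mm⁻¹ and ≥ 80 % window coverage. The discrete
   minimum is refined to sub-grid resolution by the centroid of the
   curvature-dip deficit (baseline = the larger window-edge d2 value)
   within ±0.5 mm — a non-parametric refinement that is exact for a
   symmetric dip and averages noise over the dip support.
4. **Assembly.** Valid meridians contribute (r cos θ, r sin θ, −s(θ, r));
   a contour with under half its meridians valid raises
   `TooFewValidMeridians`. NT/SI diameters are 3D chords between opposite
   cardinal meridians (at the ~2° tilts involved they differ from
   XY-projected chords by < 0.01 mm).

**Smoothing half-width.** The default is 0.6 mm. The choice is a
bias–variance argument: the Savitzky–Golay curvature estimate has noise
variance ≈ 45 σ_z²/(N_eff L⁴) with N_eff independent samples across the
window (the effective sample spacing is the generator's 0.05 mm grid, not
the 0.01 mm polar step), which at L = 0.25 mm and σ_z = 5 µm puts the
turning-point jitter near 0.1 mm — unusable — while symmetric smoothing of
a symmetric transition adds *no* location bias at any width. At L = 0.6 mm
the measured mean |error| is ≈ 0.03 mm at 5 µm noise and ≈ 1e-4 mm
noiseless. The cost is real but bounded: on *asymmetric* transitions
(scleral-blend variant, real eyes) wider windows shift the detected
minimum toward the slower-recovering side, which is why the blend
variant's truth is quoted at the blend centre with a stated displacement.
Tight closed-form derivative checks (sphere meridians) use a 0.25 mm
window, where the O(d⁴s/dr⁴·L²) smoothing bias stays below 1e-3 mm⁻¹ over
the corneal zone.

## White-to-white detection

The 256-level histogram is smoothed by a 7-level centred moving average
with symmetric (edge-reflecting) padding — which conserves the pixel total
exactly — and peaks are found with a prominence floor of 1 % of the
histogram maximum. The floor is set by the geometry of the frame: the
pupil covers ~1.5 % of a default frame, so its peak height is ~2 % of the
sclera peak; a 2 % floor would sit on top of it, 1 % passes it with margin
while still rejecting noise wiggles (histogram bin noise is ~0.2 % of the
maximum at these frame sizes). The three most prominent peaks are sorted
by *intensity* — pupil < iris < sclera — never by height.

The iris/sclera cut is the smoothed-histogram valley between the iris and
sclera peaks (the natural "dynamic threshold": every quantity derives from
the frame's own spectrum, so a constant illumination offset that clips
nothing shifts peaks and threshold by exactly that offset and leaves the
mask, contour and distances untouched). The dark class is opened once with
a 3-px disc (removing pixel bridges to lashes), the 4-connected component
containing the seed (default: frame centre) is kept, and interior holes —
pupil and any highlights — are filled. Boundary radii are traced per
degree by marching rays from the mask centroid at 0.25 px steps with
bilinear sampling and locating the outermost 0.5-crossing sub-pixel;
radii convert to mm through the anisotropic (cal_h, cal_v) calibration.
With unequal calibrations the pixel-space ray angle is reported as the
meridian angle; at clinically realistic anisotropies the angular error is
negligible, and with equal calibrations it is zero.

Registration between image and surface assumes the image principal point
(default: frame centre, configurable) maps to the surface origin with axes
aligned — the device does not publish its registration, so the δ map's
common origin is a declared convention (`origin_policy`: apex by default,
WTW centroid as the alternative).

## Contour geometry

The plane fit is ordinary least squares in z over valid points: at limbal
tilts (≲ 4°) OLS and total least squares agree to < 0.01°, and OLS is
hand-verifiable. Leveling rotates the contour rigidly about the valid
centroid to align the fitted normal with +Z; because OLS measures
*vertical* residuals, one rotation of a non-planar contour leaves
micro-degree tilt, so the alignment iterates to < 1e-9° (idempotent, and
the RMS residual is preserved up to the second-order vertical/perpendicular
difference, ~rms·tilt²).

Sagittal depths are |z| of the four clinical cardinal points of the *raw*
(unleveled) contour relative to the apex plane — leveling would partly
remove exactly the side-to-side depth asymmetry being measured. The δ map
resamples both contours to per-integer-degree polar radii about the common
origin and differences them; angles are valid only where both contours
are, and the argmax/argmin are taken over valid angles.

## Cohort statistics

`summarize` reports n, mean, sample (n−1) SD, min and max, formatted as
"mean ± STD" and "min : max" to two decimals; a single observation has SD
0 by convention. The two-sample comparison is Student's pooled-variance
t-test with two-sided p (df = n_a + n_b − 2) — the classical clinical
default — with Welch's variant behind a flag; two identical constant
samples give t = 0, p = 1 rather than 0/0. Fellow-eye pairing is
deliberately ignored (comparisons treat sides as independent samples).
`cohort_table` produces one row per (quantity, orientation) with both
sides' summaries, right-vs-left p per row, and NT-vs-SI p within each
side.

## Numerical and degenerate-input choices

* Savitzky–Golay windows are forced odd and > the polynomial order; the
  radial grid must be uniform.
* `locate_limbus_point` returns an *invalid value* (never raises) for
  monotone d2, insufficient prominence or poor window coverage; errors are
  reserved for structurally impossible inputs.
* Peak finding pads the spectrum with sentinels so maxima at levels 0 and
  255 count as peaks; with more than three candidates the three most
  prominent are kept.
* Contour CSVs write invalid meridians as NaN coordinates with a 0 flag;
  the WTW centre and laterality ride in `#` header comments so the column
  schema stays minimal. Per-meridian quality scores live in the JSON
  sidecar, not the CSV.
* Ray tracing treats pixels outside the frame as background; a mask whose
  centroid falls outside itself (extreme crescents) is rejected as
  degenerate rather than mis-traced.

## Problem sizes

Default working resolution — 0.05 mm synthetic grids (~1.1e5 points), 360
meridians at 0.01 mm steps, full 1024×1280 frames, 2000 replications for
the null-uniformity check — was chosen so a full surface fit takes a few
seconds and the entire validation suite runs in a couple of minutes on a
single CPU. Unit tests use coarser grids (90 meridians, 0.02 mm steps)
where full resolution adds nothing to the property being checked.

## Known limitations

* The turning-point detector assumes one dominant curvature transition per
  meridian; double transitions (e.g. severe peripheral distortion) would
  need the prominence gate retuned.
* Wide symmetric smoothing is unbiased only for symmetric transitions; on
  real, asymmetric limbal profiles the detected ring can shift by a few
  hundredths of a millimetre toward the flatter side.
* Image/surface registration is assumed, not estimated; δ maps inherit
  any true principal-point offset.
* The cohort layer treats eyes as independent; within-subject correlation
  between fellow eyes is not modelled.
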