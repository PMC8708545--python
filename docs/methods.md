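# Methods

This note documents the models, numerical choices, and known limitations
behind `keratoptics`.

## Schematic eye

The baseline eye is a six-surface wide-field schematic eye traced from air
to retina: biconic anterior/posterior cornea (Ry/Rx 7.480/7.517 and
6.287/6.704 mm, conics −0.130/−0.136 and −0.005/−0.303), a flat 4 mm pupil
(aperture stop), conic crystalline-lens surfaces (9.533 mm, k = −3.203;
−5.736 mm, k = −0.278), 16 mm of vitreous, and a −13 mm spherical retina;
axial thickness totals 23.829 mm.  Media: cornea 1.376, aqueous 1.3374,
vitreous 1.336, all at the single design wavelength 589 nm (the hydrogel
indices were measured there).  Chromatic dispersion, polarization, and
Fresnel losses are out of scope.

Coordinates: z along the optical axis toward the retina, positive radius =
center of curvature behind the surface.  Field angles sweep the
**transverse (x–z) plane**; this makes the cosine Zernike modes (vertical
astigmatism Z(2,2), horizontal coma Z(3,1)) the field-driven terms while
the sine modes vanish by the system's y-symmetry, matching the
aberration-versus-incident-angle analyses the package reports.

### Crystalline lens

The lens supports a polynomial GRIN profile
`n = n0 + nr2 r² + nr4 r⁴ + nr6 r⁶ + nz1 z + nz2 z² + nz3 z³ + nz4 z⁴`
(local z from the anterior lens vertex; decentration ignored).  The
numeric coefficients for the adult human lens belong to an external
age-dependent model family and are **not** packaged; they are accepted as
a configuration record (`GrinMedium`).  The default build instead uses a
homogeneous medium at the classic schematic-eye *equivalent* lens index
1.420, chosen a priori, which yields +62.35 D total power and a mildly
myopic, realistically aberrated eye.  All GRIN propagation code is
exercised against synthetic coefficient sets (homogeneous limit, SELFOC
parabolic profile with its analytic cosine ray path, 4th-order step
convergence).

GRIN rays integrate the arc-length ray equation du/ds = (∇n − (∇n·u)u)/n
with classical RK4 at a fixed 0.01 mm step (configurable), carrying the
optical path as an extra state variable; the exit-surface crossing is
resolved by bisection on the final partial step to < 1e−12 mm.

### Surfaces, intersection, refraction

Biconic sag uses the standard form
`z = (cx x² + cy y²)/(1 + √(1 − (1+kx)cx²x² − (1+ky)cy²y²))`, which
reduces exactly to the conic and spherical forms; intersections solve
Newton iterations from the tangent-plane start (tolerance 1e−12 mm, with
damped pull-back when an iterate leaves the sag domain), and refraction is
exact vector Snell with TIR detection.  Semi-apertures default to 5 mm for
cornea/spectacle surfaces (15 mm for the spectacle lens itself) and the
stop radius to 2 mm; these are not printed anywhere authoritative and are
configurable.

## Wavefront sampling and Zernike analysis

For each field angle a bundle is aimed through a regular grid of
aperture-stop coordinates (fixed-Jacobian Newton aiming, residual
< 1e−8 mm).  OPD is referenced to the chief ray on the exit-pupil sphere
centered at the chief ray's retinal intersection; the exit-pupil axial
position comes from extrapolating the image-space chief ray (of a 0.25°
auxiliary field when on axis) to its axis crossing.  An object vergence
option supports the −1.4 D near-focus conjugate used when capturing
phase-plate baselines; design optimization and Strehl evaluation use the
distance (0 D) conjugate, since the design targets are distance-vision
aberrations.

Fitting uses linear least squares against the 15 OSA/ANSI modes (n ≤ 4),
normalization `N = √(2(n+1)/(1+δ_m0))`, cosine for m ≥ 0 / sine for m < 0.
A 64-point-per-side pupil grid changes no fitted coefficient by more than
0.001 µm relative to 128; 32 is used inside optimization loops.

## Imaging and Strehl

PSFs are `|FFT(pupil · exp(i2π OPD/λ))|²` with 4× zero padding,
sum-normalized; the wavefront entering the PSF is the fitted 15-mode
reconstruction with piston/tip/tilt removed (they shift, not blur).  The
Strehl ratio is aberrated peak over aberration-free peak with identical
sampling — the conventional orientation, which keeps it in [0, 1].
Retinal images convolve a letter scene (built-in antialiased 5×7 stroke
glyphs, no font dependency; 0.025 mm height = 20/20) with the OTF, on a
retinal pixel pitch derived from the model's own chief-ray image scale
(≈0.29 mm/deg); imaging is evaluated on the retina vertex tangent plane,
a negligible approximation over a 0.025 mm patch.

The "standard Zernike phase plate" is an ideal OPD screen conjugate to the
pupil: per-field baseline coefficient vectors captured from a reference
system and subtracted from every subsequent wavefront.  Applying a
system's own plate cancels every carried mode to < λ/1000 and restores
Strehl 1.000; residual fit error beyond n = 4 is genuine higher-order
content a 15-mode plate cannot remove.

## Design cases and optimization

Merit: `F = √(Σ Wᵢ(Vᵢ−Tᵢ)²/Σ Wᵢ)` over 12 Zernike operands
(piston/tip/tilt excluded) × 5 fields at weight 10, plus structural
operands at the protocol weights (radii/thicknesses 10⁶, conics 1)
implemented as *range-violation* penalties — zero inside the design
ranges (anterior radius 7.00–8.16 mm, posterior 6.00–6.90 mm, conics
−0.3–0, thickness 0.5–0.56 mm, chamber 2.91–3.65 mm), which are also hard
optimizer bounds.  Pinning the structural operands to fixed anatomical
values at weight 10⁶ would contradict the observed freedom of optimized
radii inside the range, so the boundary-operand reading is used.

Cases: `with_glasses` targets the baseline eye-plus-spectacles
aberrations (implant should mimic the natural cornea under the patient's
correction; its Strehl is evaluated through the phase plate captured from
that reference, i.e. relative to the reference system);
`without_glasses` targets zero (implant corrects the eye; Strehl is
evaluated against the diffraction limit, no plate).  The spectacle lens is
an asymmetric concave N-BK7 element (center thickness 0.600 mm) worn
5.000 mm before the cornea.

The optimizer is bounded trust-region-reflective least squares (scipy)
with seeded multi-start jitter; deterministic per seed, ties broken by
lowest merit then lexicographically smallest parameter vector.  It
reproduces the characteristic stall of weighted least-squares lens
design: defocus and astigmatism dominate the descent; coma and spherical
aberration trade against each other afterwards.

Mold tolerance multiplies the anterior and posterior sagittal radii Ry by
(1 + tol), |tol| ≤ 1%, thickness and conics unchanged (Rx follows Ry for
rotationally symmetric shapes so the shape class is preserved); the sweep
reports (tolerance, radii, on-axis Strehl) rows.

## What the homogeneous-lens default implies

Two behaviours differ from a GRIN-lens eye and bound what passing tests
demonstrate:

* The GRIN lens contributes negative spherical aberration and flattens
  the off-axis astigmatism.  With the homogeneous equivalent lens,
  ~0.11 µm of residual spherical aberration remains that cornea
  asphericity inside the bounded design range cannot remove without
  worsening oblique astigmatism, so absolute case-2 Strehl ratios land
  near 0.1–0.25 rather than above 0.9; the *orderings* (zero tolerance
  best; added asphericity helps) are the robust statements.
* With larger oblique astigmatism, the optimal biconic acquires a
  deliberate conic asymmetry (a field-constant Z(2,2) offset that halves
  the summed astigmatism operands); in a GRIN-lens eye the symmetric
  solution is optimal and biconic ≈ aspherical.  The recovered biconic
  radii still match to < 1%, but the conics differ by ~0.2.

## Synthetic data

The defective-eye generator perturbs the cornea (common radius scale →
defocus; Ry/Rx differential → astigmatism; alternative channels: conics,
chamber depth) and calibrates the perturbation by alternating 1-D secant
iterations against the measured on-axis wavefront, within ±10% of the
baseline anatomy.  Targets are aberration *increments* over the baseline,
so a zero target returns the baseline unchanged.  Gaussian OPD noise is
available for fitting studies (the study itself states none).  Generators
are pure functions of their seeds.

What synthetic eyes do not emulate: population biometry covariance,
irregular (non-conic) corneal topography, scattering media — conclusions
about those require measured patient data.

## Problem sizes

Default desk-scale settings: 32²-point pupil grids inside optimization
(64² for reported wavefronts, 128² + 4× padding for PSFs), optimizer
budgets of ~80/220/420 merit evaluations for spherical/aspherical/biconic
shapes, one optimizer start in scripted runs.  These reproduce the
qualitative results; larger grids and multi-start budgets refine absolute
values only marginally (coefficients are grid-converged to 0.001 µm at
64²).
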