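# Methods

This note records the models, conventions, parameter choices, and known
limitations behind `polspim`, in the spirit of a package's methods
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## ODF representation

A voxel's orientation distribution function (ODF) counts dipole *axes* per
solid angle.  Axes are unsigned, so ODFs are antipodally symmetric and
contain only even spherical-harmonic bands; the imaging physics (products
of two degree-2 polynomials in the direction) band-limits transmission to
ℓ ≤ 4.  We therefore store 15 real coefficients per voxel.

* Basis: real, orthonormal spherical harmonics **without** the
  Condon–Shortley phase; m > 0 ↔ cos(mφ), m < 0 ↔ sin(|m|φ).
* Flat ordering ("even-l4-v1", also the on-disk channel order):
  (0,0), (2,−2) … (2,2), (4,−4) … (4,4).
* Quadrature: Gauss–Legendre in cos θ (16 nodes) × uniform azimuth
  (24 nodes), 384 points, exact for spherical polynomials to degree 15 —
  comfortably the degree-8 products that projection of degree-4 functions
  requires.  The grid is antipodally symmetric by construction.
* Peaks: dense Fibonacci-hemisphere argmax (8000 directions for single
  ODFs, refined by a local Nelder–Mead on the sphere; 4000 unrefined for
  whole fields, ≈1° grid error).  Axes are canonicalized to z ≥ 0 (ties:
  y ≥ 0, then x ≥ 0).  ODFs with relative contrast (max−min)/mean|Ψ| below
  1e−3 are flagged degenerate instead of being assigned a noise direction.
* GFA (generalized fractional anisotropy) = std/rms of the ODF over the
  sphere = √(1 − F₀₀²/ΣF²) for an orthonormal basis; both forms are
  computed and tested against each other.

## Optical model

Lab frame: ẑ = detection axis of view A (NA 1.1), x̂ = detection axis of
view B (NA 0.67), ŷ = shared lateral axis; water immersion n = 1.33;
defaults λ_ex = 488 nm, λ_em = 500 nm.

* **Excitation**: polarized light excites a dipole with efficiency
  |ŝ·p̂|².  Tilting the sheet by τ rotates the propagation axis within the
  sheet plane, k̂(τ) = cos τ d̂_illum + sin τ ŷ; the polarization angle ψ
  is measured in the plane ⊥ k̂ from the detection objective's axis.
* **Detection**: a dipole's normalized sin² emission pattern integrated
  over the collection cone of half-angle arcsin(NA/n) gives efficiency
  C₁ + C₂ sin²φ_d.  C₁, C₂ come from numerical integration of the cone
  integral (the closed-form antiderivative serves as an independent test
  oracle).  C₂ = 0 at NA = n; C₁ → 0 in the paraxial limit.
* **Dipole PSFs**: a scalar-pupil vectorial model — the dipole far field
  is projected onto the p/s basis, rotated through an aplanatic lens
  (1/√cos θ apodization, anti-aliased aperture edge), and Fourier
  transformed; intensity is quadratic in the dipole components,
  PSF(x; ŝ) = Σ M_ab(x) s_a s_b.  This reproduces the Airy-like transverse
  and donut-shaped axial morphology; full Richards–Wolf with index
  mismatch is out of scope.  Each dipole channel's PSF energy is matched
  exactly to the cone integral, making the DC limit of the coupled model
  identical to the angular response.
* **Transfer functions**, two fidelity modes:
  - *factored*: H_pv,ℓm(ν) = B_pv(ν) · a_pv,ℓm with a the SH coefficients
    of the angular response and B a scalar OTF — circular-pupil ("chat")
    transverse OTF with exact cutoff 2NA_v/λ times a Gaussian along the
    detection axis with σ_ax = (σ_ls⁻² + σ_det⁻²)^(−1/2) (the uniform
    light-sheet assumption; σ_ls default 600 nm, σ_det defaults to the
    diffraction-scale 2nλ/NA² FWHM).
  - *coupled*: per-(ℓ,m) spatial kernels from the frequency-domain
    cross-correlations M̂_ab(ν) of the vectorial pupil fields contracted
    with the excitation dyad tensor, so the spatial shape varies with
    (ℓ,m) and axial–transverse PSF interference weakly transmits
    components that vanish at ν = 0.
* **Photon normalization**: responses are scaled so an isotropic
  unit-density ODF yields signal 1.0 in the brightest untilted
  measurement; real-instrument gain calibration is out of scope.

## Angular holes and scheme audit

The audit builds the n_meas × 15 angular matrix at ν = 0 in the
detection-aligned harmonic frame.  An **angular hole** is an individual
harmonic whose transmitted column norm is below 1e−3 of the largest — for
the untilted six-measurement scheme these are (2,1), (4,±3), (4,1),
exactly zero at ν = 0 because untilted illumination from view A produces
weights with no z-dependence and from view B none in x, so no odd-x·odd-z
monomial ever appears.  The full SVD additionally reports rank, nullity
and orthonormal null vectors (a scheme of one repeated measurement has
rank 1, nullity 14).

Through the *coupled* transfer function the holes are not exactly null at
ν ≠ 0: axial–transverse pupil interference transmits them weakly.  The
frequency-diverse audit therefore reports per-coefficient RMS amplitudes
over a transverse frequency grid, from which the hole's fold-reduction
(median of band-mates / weakest member) is finite — ≈40× for (2,1) under
the untilted scheme in this model.  One ν = 0 null *direction* (a mix of
(4,−2) and (4,−4)) is not a hole in this per-harmonic sense: it is filled
strongly by transverse–transverse frequency diversity, which is why the
hole count is four, not five.

**Scheme search**: candidates are (view, ψ, τ) with ψ ∈ {0°,…,150°} in 30°
steps and τ ∈ {−20°, 0°, +20°} (36 candidates; choosing 6 spans ≈1.9×10⁶
schemes).  The search minimizes the condition number κ of the ℓ ∈ {0,2}
submatrix by seeded randomized sampling plus deterministic greedy swaps;
`balanced=True` restricts to three illuminations per view, matching the
instrument's interleaved acquisition and keeping both detection arms'
spatial resolution in play.  The frozen `six_with_tilt` preset is the best
balanced result over seeds 0–7 (κ = 10.38); it has full ℓ ∈ {0,2} rank and
a single residual ℓ = 4 hole, consistent with partial ℓ = 4 recovery.
Untilted candidates can never reach full rank — the (2,1) column is
structurally zero — and 5 measurements are fewer than the 6 unknowns, so
the minimum full-rank count is 6.

## Forward simulation and noise

The forward model multiplies the field's coefficient spectra by H and
inverse-transforms (FFT, circular boundaries; default 16-voxel zero
padding suppresses wraparound for compact objects).  Poisson noise draws
counts at a configurable photons-per-signal-unit gain; Gaussian read noise
is also available.  All randomness is seeded and recorded in the stack's
metadata.

## Reconstruction

Per spatial frequency, the ridge estimate F̂ = Hᴴ(HHᴴ + ηI)⁻¹G (the
n_meas × n_meas form of the normal equations; identical to
(HᴴH + ηI)⁻¹Hᴴ).  Outside every view's transverse support H = 0 and the
estimate is zero; frequencies covered by a single view use that view's
rows only, automatically, because the other rows vanish there.  η = 0
falls back to a cutoff pseudo-inverse with a warning.  Counts are divided
by the recorded gain so η is defined on the photon-normalized signal
scale.  The default η = 3e−3 was chosen by an L-curve-style sweep on the
noisy GUV phantom: the peak-recovery fraction is flat (≥98%) from 1e−3 to
3e−2, and 3e−3 sits at the residual/energy elbow.  No positivity or
smoothness constraint is applied by default; an optional density clamp is
flagged in the output metadata.

With six measurements the per-frequency system is underdetermined
(6 equations, 15 unknowns): the estimator returns the minimum-norm
consistent solution, i.e. the projection of the truth onto the transfer
operator's row space.  Round-trip tests therefore compare against the
per-frequency row-space projection of the ground truth inside the common
frequency support ("recoverable subspace"); raw-truth correlations
additionally confirm that the untilted scheme's (2,1) channel is *not*
recovered while its band-mates are.

## Synthetic data

The generators produce the study's test objects with exact ground truth:

* **Watson ODFs** exp(κ(ŝ·μ̂)²), unit mass: the canonical two-parameter
  axial family (dumbbell κ>0, pancake κ<0); |κ| beyond the ℓ ≤ 4
  band limit triggers an aliasing warning.  Study default κ = 5.
* **GUV**: spherical shell (default radius 3 µm — a ~6 µm vesicle — width
  390 nm) of membrane-normal (or tangential) Watson ODFs on a 64³ grid of
  130 nm voxels.
* **Fibers**: tubes of tangent-aligned Watson ODFs along polylines;
  overlaps sum (multi-lobed crossings).
* **Nanowire fixtures**: 'single'/'paired'/'crossed' ~200 nm wires lying
  in the coverslip plane of the dual-view geometry (spanned by ŷ and
  (x̂−ẑ)/√2); fibers blend the tangent families of all wires in reach by
  proximity, so crossings produce multi-lobed ODFs and elevated radiality.

What the generators do **not** emulate: photophysics (bleaching,
lifetime, saturation), spatial diffusion or sample motion, deskew and
dual-view registration errors, wavelength-dependent calibration, and
aperiodic backgrounds.  Passing tests demonstrate the correctness of the
model/inversion chain under the quasi-static, registered, shot-noise-
limited regime — not performance on raw instrument data.

## Numerical choices and degenerate inputs

* Quadrature tolerances: orthonormality/Parseval to 1e−8/1e−6; DC
  equivalences to 1e−6.
* Structural-null threshold 1e−3 × largest singular value (the measured
  gap at ν = 0 is exact-zero vs ≥1e−2, so the choice is uncritical);
  hole amplitude criterion: 10-fold below the band median.
* Degenerate peaks: relative contrast < 1e−3 → flagged, never reported as
  a direction.  GFA of an all-zero ODF raises instead of returning 0.
* Aspect ratio of a degenerate (coplanar/collinear) mass returns +inf
  with the smallest eigenvalue test at 1e−12 relative.
* Radiality excludes voxels within 1 nm of the wire axis (undefined
  perpendicular) and reports the exclusion count.
* Noiseless problem sizes in the tests (48³ GUV round trips, 64³ noisy
  benchmark, 24-voxel wire fixtures) keep the full suite at a few minutes
  on a single CPU while staying above the scales where the physics is
  resolved (voxels ≤ half the transverse resolution).

## Known limitations

* The factored mode treats each view's OTF as orientation-independent;
  spatio-angular coupling enters only through the coupled mode, which is
  used for audits and supported (at small volumes) in reconstruction.
* The voxel pitch of 130 nm cannot carry the full 2NA/λ support of the
  1.1 NA view (the model warns); reconstructions are correspondingly
  band-limited.
* Elongated objects whose spectra fall where only one view has support
  inherit that view's 3-row angular limitation; peaks of fat fiber halos
  aligned with a detection axis can be biased tens of degrees even without
  noise.  Objects in the coverslip plane — the physically relevant
  orientation — reconstruct accurately (the zero-disorder wire fixture
  reaches mean parallelism ≥ 0.99 after a noiseless round trip).
* Odd-ℓ information, ℓ ≥ 6 bands (two-photon), SO(3) distributions for
  misaligned excitation/emission dipoles, and real-data preprocessing are
  out of scope.
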