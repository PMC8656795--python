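# Methods

## Forward model

Spatially modulated diffuse reflectance of a semi-infinite homogeneous
turbid medium is evaluated with the standard diffusion-approximation
closed form.  With absorption μₐ and reduced scattering μ′ₛ (mm⁻¹),
transport coefficient μ_tr = μₐ + μ′ₛ, reduced albedo a′ = μ′ₛ/μ_tr and
spatial frequency f_x (cycles/mm):

    μ′_eff = √(3 μₐ μ_tr + (2π f_x)²)
    R_d(f_x) = 3 A a′ / ((μ′_eff/μ_tr + 1)(μ′_eff/μ_tr + 3A))

where A = (1 − R_eff)/(2(1 + R_eff)) and R_eff(n) ≈ 0.0636 n + 0.668 +
0.710/n − 1.440/n² is the effective internal reflection coefficient of
the boundary.  Default refractive index n = 1.4 (typical soft tissue).

Assumptions: scattering-dominated medium (μ′ₛ ≫ μₐ), flat sample, planar
illumination, no layering.  A genuine property of this closed form worth
knowing: at the high frequency (f_x = 0.2 mm⁻¹) R_d is *not* strictly
decreasing in μₐ near the validity edge of the model — at μ′ₛ = 0.5 mm⁻¹
(μ′ₛ/μₐ ≈ 10) the (2πf_x)² term dominates μ′_eff and the μₐ ordering
inverts by a few 10⁻⁴.  Inside the scattering-dominated bulk of the
domain (μ′ₛ ≳ 0.7 mm⁻¹) the expected monotonicities hold, and the
inversion uses both frequencies jointly, so this corner behaviour does
not harm recovery.

## LUT and inversion

The look-up table tabulates (μₐ, μ′ₛ) → (R_DC, R_AC) on a 201-point
log-spaced μₐ grid over [0.001, 0.1] mm⁻¹ × 201-point linear μ′ₛ grid
over [0.1, 5] mm⁻¹ — a superset of the tissue-mimicking phantom range
(μₐ 0.005–0.05, μ′ₛ 0.5–3 mm⁻¹) to give headroom for noisy pixels — at
the frequency pair (0, 0.2) mm⁻¹.  The LUT file format is a
self-describing CSV, so an externally generated table (e.g. Monte Carlo)
can be swapped in without code changes.

Inversion is a nearest-node search (k-d tree in reflectance space)
followed by up to 12 damped Gauss–Newton steps on the bilinear
interpolant of the table, with steps clamped to one cell and iterates
clamped to the grid.  Reflectance pairs outside the image of the LUT
converge to a boundary point with non-vanishing residual and are flagged
(`QC_OUT_OF_RANGE`) rather than silently clamped; NaN inputs propagate
as flagged NaNs.  Measured on the phantom range, round-trip error is
~0.004 % median / <0.04 % max — far inside one grid cell.

## Demodulation

**Three-phase.** For frames at phases 0, 2π/3, 4π/3 the root-sum-of-
squared-differences identity recovers the AC amplitude and the frame
mean recovers DC, exactly, per pixel, for any global phase.  This is the
reference method.

**Single-snapshot.** The single frame is reflect-padded along the
modulation axis (suppressing FFT leakage from the non-periodic border),
transformed per row, and split at half the carrier frequency k₀ with
raised-cosine transitions of half-width k₀/4: the low band is inverse-
transformed to M_DC; the one-sided band around +k₀ (upper roll-off
mirrored at 2k₀ − split) gives the complex envelope, and M_AC = 2|z|.
Filtering is 1D per row because the projected pattern is a line grating;
a 2D filter would couple rows without benefit for this geometry.  The
declared edge margin is 3/k₀ pixels (30 px at 0.2 mm⁻¹ and 0.5 mm/pixel);
interior error on flat scenes is < 0.4 %, and ringing also appears
within the same margin of any step discontinuity in the scene — the
classic SSOP edge artifact.  Filter split, transition width and margin
factor are configurable (`SSOPFilterConfig`).

**Conventions.** Frequencies in cycles/mm are converted to cycles/pixel
in exactly one place (`fx_to_cycles_per_pixel`).  Both M_DC and M_AC are
taken from the modulated stack (M_DC = gain·R_d(0)/2 under the rendering
convention); when a planar f_x = 0 stack is present its mean, halved,
replaces M_DC.  Any consistent convention cancels in calibration because
the reference is processed identically.

## Calibration

R_d,sample = (M_sample/M_ref) · R_d,model(ref_op, f_x) per frequency.
Pixels where the reference amplitude falls below 10⁻⁶ of its maximum are
masked, not divided.  Sample and reference must share the illumination
geometry; there is no 3D profile correction (flat-scene assumption).
The calibration phantom's true properties are a user input; the default
standard (μₐ = 0.01, μ′ₛ = 1.0 mm⁻¹, n = 1.4) sits mid-range.

## Hemoglobin unmixing

μₐ(λ) = ln10·[ε_HbO₂(λ)·C_HbO₂ + ε_Hb(λ)·C_Hb] is solved per pixel in
closed form at the wavelength pair (default 665/860 nm: deoxy-dominant
red + oxy-dominant NIR, straddling the ~800 nm isosbestic point).  The
packaged extinction table (600–1000 nm, 10 nm grid, decadic convention,
cm⁻¹ M⁻¹ in the file, converted to mm⁻¹ mM⁻¹ on load) is an interpolated
compilation of the standard published hemoglobin spectra; a
condition-number guard (< 10⁶) rejects degenerate wavelength pairs.
Negative concentrations are flagged, never truncated, before StO₂;
StO₂ = 100·C_HbO₂/(C_HbO₂+C_Hb) is clamped to [0, 100] with the clamp
recorded per pixel, and undefined (total ≤ 0) pixels are NaN + flag.

## Synthetic scenes

The generator renders frames through the *same* diffusion forward model
the inversion uses:

    I(x, y) = gain(x, y) · ½ [R_d(0) + R_d(f_x) cos(2π f_x x + φ)] + noise

with a smooth Gaussian vignette gain (peak 1.0, ≈0.72 at the corners) to
exercise calibration's gain cancellation, optional Poisson shot noise
(default budget 10⁴ photons per unit intensity) and Gaussian read noise.
All randomness flows through one seeded generator; identical seeds give
bit-identical stacks.

Scene layouts: `flat`, `step`, `inclusion`, and `four_roi` — a
perfusion-study layout with four rectangular ROIs (A/C/F perfused at
70/73/75 % StO₂, R ischemic at 30 %, total hemoglobin 0.05 mM, μ′ₛ
1.2/1.0 mm⁻¹ at 665/860 nm), whose absorption maps are produced by the
Beer–Lambert forward mix so the end-to-end truth is exact.  Default
image size is 256×320 at 0.5 mm/pixel — a quarter-scale sensor that
keeps the 0.2 mm⁻¹ pattern well below Nyquist and whole-pipeline runs in
seconds.

What the generator does *not* emulate: curved surfaces and height
variation (no profilometry), speckle, specular reflection, chromophores
other than hemoglobin, lateral light transport across property
boundaries (each pixel is rendered from the semi-infinite homogeneous
model).  Passing tests therefore validate the processing chain and its
numerics, not instrument-level absolute accuracy on real tissue.

The ischemia time course models six subjects × four ROIs × five
timepoints (T0..T60).  The resected ROI decays exponentially
(τ = 20 min) from baseline toward a 25 % floor; perfused ROIs hold
baseline with a 2 % between-subject shift and 1 % measurement jitter.
Lactate follows the monotone link `base + k·(100 − StO₂)/100 + ε`,
base 1.5 mmol/L, coupling k = 6 mmol/L over the full desaturation range,
ε ~ N(0, 0.4 mmol/L).  Only the monotonicity and the negative sign of
the StO₂–lactate coupling are treated as biologically anchored; the
exponential shape and the parameter values are modeling choices sized to
produce a strong (r ≈ −0.93 at seed 1), not perfect, anticorrelation.

## Statistics

Pearson r with Fisher-z 95 % CI (`tanh(atanh r ± 1.96/√(n−3))`) and the
two-sided p-value from the exact beta-distribution test.  Two-group
discrimination reports the Mann–Whitney AUC (half-weight ties; equal to
the trapezoidal ROC area), a DeLong CI from placement values, and the
Youden-optimal cut-off with ties broken toward the lower threshold.
Normalization to ROI-A at T0 is per subject, applied to mean and SEM
(and optionally lactate), idempotent by construction.

## Problem sizes and tolerances

Tests and the acceptance script run on 256×320 scenes, the 201×201 LUT,
100-case property sweeps and the 6×4×5 time course — sizes chosen so the
full suite completes in well under a minute on one core while leaving
every error budget (1 % demodulation/calibration interiors, one LUT cell
for inversion, machine precision for the linear algebra) comfortably
resolvable above numerical noise.
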