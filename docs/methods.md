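# Methods

This note documents the models, numerical choices and limitations behind
`ccodot`. Units throughout: lengths in mm, absorption and reduced
scattering in mm⁻¹, concentrations in µM, specific absorption coefficients
in µM⁻¹·mm⁻¹ (loaders convert the conventional mM⁻¹·cm⁻¹ by 1e-4),
attenuation in OD (log10).

## Spectra and pathlength models

Three chromophores are supported: HbO2, HHb and oxCCO, the last
represented by its **oxidized-minus-reduced difference spectrum** — the
quantity that multiplies a redox-state change Δ[oxCCO]; its sign
convention means a positive Δ[oxCCO] (oxidation) adds absorption in
proportion to that difference spectrum. The packaged tables
(`src/ccodot/data/*_synthetic.csv`, 700–1000 nm at 2 nm) are smooth
monotone-cubic curves anchored to widely cited literature values (their
headers say so); they are synthetic stand-ins, adequate because every
quantitative test generates and inverts data with the same tables. Users
can substitute their own two-column CSVs.

The differential pathlength factor (DPF) enters only the channel-space
Beer–Lambert fit. The packaged adult-head model declines smoothly from
~6.4 at 740 nm to ~5.7 at 900 nm; `constant_dpf(6.0)` is a fallback.
With a constant DPF all channel concentrations are scaled uniformly across
wavelengths, so spectral shapes survive but absolute µM values inherit any
error in the constant.

## Preprocessing

Attenuation conversion uses an arbitrary reference intensity (default
1e5); the additive constant it introduces is removed by filtering.
Filtering is **zero-phase** (forward–backward, `sosfiltfilt`), chosen so
block-averaged responses are not phase-shifted; the effective gain is the
squared Butterworth magnitude response. Records shorter than the filter's
padding length (31 samples for the default 5th-order band-pass) are
rejected rather than padded.

Block averaging re-zeroes each epoch at its own onset sample before
averaging (mean change *relative to stimulus onset*); this is switchable
(`rezero=False`). Note that re-zeroing adds the onset sample's noise to
every sample of that epoch, so the averaged output variance is
2σ²/n_epochs at other samples — the factor-of-n reduction holds relative
to a single re-zeroed epoch.

Wavelength selection takes the nearest measured sample (ties toward the
lower wavelength) rather than interpolating: broadband CCD bins are dense
(≲2 nm) relative to the 10 nm reconstruction grid.

## Forward model

Continuous-wave diffusion approximation,
−∇·(κ∇Φ) + μa Φ = q with κ = 1/(3(μa+μs′)), discretized by a
finite-volume 7-point stencil on a regular voxel grid with harmonic-mean
face diffusivities. The matrix is symmetric positive definite; solves use
Jacobi-preconditioned conjugate gradients at rtol 1e-12 (a sparse LU was
20–40× slower on these systems). The boundary condition is Robin
(partial-current), Φ + 2AκΦ′ = 0, with A from the Groenhuis polynomial at
refractive index 1.4; pure Neumann is available (`boundary="neumann"`) but
is non-physical for a diffuse air–tissue interface and singular at zero
absorption. Optodes become unit-power Gaussian profiles (σ = 2 mm,
truncated at 3σ) on the nearest face of the bounding box; σ = 0 gives a
delta. A detector reading is the fluence sampled with the detector
profile, making reciprocity exact by matrix symmetry.

Sensitivities use the Rytov (log-attenuation) linearization:
J(ch, v) = Φ_src(v) Φ_det(v) V_v / (y_ch ln 10), the derivative of channel
log10-attenuation with respect to voxel μa. Against a nonlinear re-solve
this is accurate to ~0.4% for a uniform 1e-4 mm⁻¹ perturbation and ~1–3%
for sparse perturbations up to 1e-3 mm⁻¹. The on-axis decay under a point
source at depth 1/μs′ matches the extrapolated-boundary semi-infinite
Green's function to within ~7% (normalized profile, 3–20 mm) on a 1 mm
grid.

Grid projection between forward and reconstruction grids uses exact
rectilinear interval overlaps; intensive fields are volume-weighted means
(integral-preserving on the common support), Jacobian rows are aggregated
by summation so that J·Δμa is exactly preserved for absorption fields
constant on target voxels.

The default phantom is a three-layer slab (scalp+skull 12 mm, CSF 2 mm,
brain) on a 108 × 63 × 42 mm domain — wide enough for the 90 mm array
footprint — at 2 mm spacing. Tissue optical properties ship as a
documented synthetic per-tissue table (μs′ power laws, blood+water-shaped
μa), overridable via CSV. The thin CSF layer is handled by the diffusion
approximation only approximately (it is a low-scattering channel where
diffusion theory is known to be weakest); μs′ = 0.3 mm⁻¹ is the usual
effective value.

## Synthetic acquisition

`make_array()` reproduces a three-row holder: 4 sources in the middle row,
two rows of 7 detector slots at ±10 mm, 15 mm within-row pitch, sources
staggered half a pitch; each source pairs with its 8 nearest detectors →
32 channels at two separations (12.5 and 24.6 mm), overlapping and
multidistance.

The activation blob is a raised-cosine sphere restricted to brain voxels.
Defaults: radius 15 mm, center (39, 31.5, 18) mm — lateralized and at the
cortical surface, emulating the extent and placement of a full-field
checkerboard V1 response; peak amplitudes +1.0 / −0.3 / +0.1 µM for
HbO2 / HHb / oxCCO (oxCCO an order of magnitude below hemoglobin — though
only ~2× smaller in Δμa terms, since its difference-spectrum extinction is
~5× larger). The time course is a trapezoid: 5 s rise, plateau to
stimulus end (20 s), 10 s fall, over a 20 s + 20 s × 10-epoch block
design at 1 Hz (400 s). These produce channel attenuation changes up to
~1e-4 OD, the scale of real broadband recordings.

Channel data are generated through the wavelength Jacobians (linearized
forward model) and wrapped as positive intensities about the modeled
channel baseline, so the full preprocessing chain runs on realistic raw
data. Noise is seeded additive Gaussian attenuation noise (default sd
5e-4 OD per sample). For **inverse-crime control** the data are generated
with Jacobians from an independently discretized phantom at 2× the
resolution of the reconstruction operator's forward grid (1.5 mm vs
3 mm), so matched-operator shortcuts are unavailable. What the generator
does *not* emulate: physiological noise (Mayer waves, cardiac),
superficial hemodynamics, motion, optode-coupling drifts — so passing
tests demonstrate method correctness, not robustness to structured
real-world confounds.

## Inverse problem

The multispectral operator stacks J_λ ε_λ^c blocks (wavelength-major rows,
chromophore-major columns) and is applied matrix-free. Reconstruction
minimizes ‖ΔA − JΔC‖²_{Γe⁻¹} + λ‖∇ΔC‖²_{Γx⁻¹} with Γe = I (a diagonal
override is accepted) and Γx⁻¹ = diag(C_b)⁻², realized as the augmented
least-squares system [J S; √λ L] on sphered unknowns z = ΔC/C_b, with
S = diag(C_b) (56 / 24 / 12.8 µM; the oxCCO background reflects its
higher visual-cortex concentration) and L the per-chromophore,
per-axis forward-difference gradient with zero-gradient (reflective)
boundary rows omitted. Because C_b is scalar per chromophore, sphering
before or after the gradient is identical, which fixes the convention the
functional leaves open. λ applies to the *sphered* penalty; the exact
identities that follow are tested (solution linearity in the data;
invariance under C_b → sC_b with λ → s²λ).

LSQR starts from zero (deterministic; ΔA = 0 returns exactly zero), capped
at 50 iterations, tolerance 1e-5 — these defaults follow standard
practice for this problem class; the dense-oracle tests raise the caps to
isolate solver convergence from formulation. λ defaults to 1e-4 and an
L-curve selector (maximum finite-difference curvature of the log–log
residual/penalty curve over a ≥2-decade grid) is provided. Reconstruction
is per time frame; no temporal regularization. The default reconstruction
grid is the forward grid coarsened to 3 mm (the projection also breaks
exact operator matching in the default pipeline); a 40-sample
block-averaged epoch's "40 s" display frame is its last sample.

Residuals are computed in reconstruction voxel space, before any surface
mapping. `surface_project` averages voxel values within a 3 mm radius of
each surface node and flags (NaN) nodes with no voxel in range.

## Expected performance and known limitations

With the default 32-channel, two-distance array through a 14 mm
superficial layer, the operator's rank is at most
n_channels × n_chromophores (the wavelength dimension spans only the three
extinction spectra), and the point-spread function is depth-elongated and
superficially biased. Consequences, measured on the default phantom
(noiseless):

- the activation is localized laterally to within a voxel and its
  centroid to well within one blob radius, with correct signs for all
  three chromophores;
- the reconstructed depth is biased toward the surface, and voxelwise
  spatial correlation with the compact truth saturates near 0.4 (0.29 for
  HHb) — this is a ceiling of the smoothness-regularized formulation with
  this array, not a solver artifact: the same solver exceeds 0.9
  correlation on a full-column-rank toy system, and the exact regularized
  minimizer (dense dual solve) across λ = 1e-2…1e-8 does no better;
- at the default noise (5e-4 OD/sample) the 20 s frame carries a
  matched-filter SNR of ≈ 4 summed over all 544 measurements, so noisy
  single-session images are noise-dominated; channel-space detection and
  the noiseless/inverse-crime analyses are the meaningful regimes at desk
  scale.

The two- vs three-chromophore residual difference in over-blob channels
correlates up to ~0.8 with the oxCCO difference spectrum and peaks at
810 nm (vs the 830 nm extinction peak): the two-chromophore model absorbs
part of the oxCCO signature into HbO2, leaving a −HbO2 component mixed
into the difference spectrum — the same contamination seen in real
broadband studies. Channels farther than two blob radii carry < 5% of the
over-blob difference norm.

Problem sizes were chosen for a single desk CPU: 2 mm forward grids
(~36k voxels, 17 wavelengths ≈ 20 s of Jacobian computation), 3 mm
reconstruction grids (~33k unknowns, LSQR in seconds), 1.5 mm
inverse-crime simulation (~85k voxels, ≈ 1 min). A subject-specific
head-mesh workflow (MRI segmentation, FEM meshing, atlas registration,
GM-surface rendering) is out of scope; an unstructured-mesh backend is an
extension point.
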