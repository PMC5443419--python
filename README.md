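# ccodot

Broadband diffuse optical tomography (DOT) of hemodynamics **and
metabolism**: volumetric reconstruction of oxy-hemoglobin (Δ[HbO2]),
deoxy-hemoglobin (Δ[HHb]) and oxidized cytochrome-c-oxidase (Δ[oxCCO])
concentration changes from multi-wavelength near-infrared attenuation
measurements.

Standard fNIRS/DOT images hemoglobin only, an indirect marker of brain
activity that fails when neurovascular coupling is impaired. Broadband
systems additionally resolve the redox state of cytochrome-c-oxidase — the
terminal enzyme of the mitochondrial respiratory chain and a direct marker
of cellular oxygen metabolism — whose concentration is an order of
magnitude below hemoglobin's. `ccodot` implements the full pipeline needed
to image all three chromophores from a 32-channel broadband acquisition,
together with a synthetic-data generator so every stage is testable with
known ground truth. It is aimed at researchers in diffuse optics and
functional neuroimaging methods.

## Method

Raw intensities are converted to attenuation changes
`ΔA_λ = log10(I0 / I_λ)`, band-pass filtered (5th-order Butterworth,
0.01–0.25 Hz, zero-phase), block-averaged over stimulation epochs
(20 s stimulation / 20 s rest × 10), and subsampled to 17 wavelengths
(740–900 nm in 10 nm steps).

Two analyses share these data:

- **Channel-space spectroscopy** (modified Beer–Lambert, UCLn-style):
  per channel, `ΔA(λ) = Σ_c ε_c(λ) ΔC_c · d · DPF(λ)` is solved by least
  squares over wavelengths, with `d` the source–detector distance and DPF
  the (wavelength-dependent) differential pathlength factor.

- **Multispectral image reconstruction**: a continuous-wave
  diffusion-approximation forward model
  `−∇·(κ∇Φ) + μa Φ = q`, `κ = 1/(3(μa + μs′))`, discretized with a
  finite-volume 7-point stencil on a layered head phantom (Robin boundary
  condition), yields per-wavelength Rytov sensitivity matrices
  `J_λ(ch, v) = Φ_src Φ_det V_v / (y_ch ln 10)`. Stacking `J_λ ε_λ^c`
  blocks over wavelengths and chromophores gives the multispectral system
  `ΔA = J ΔC`, solved as

  `min_ΔC ‖ΔA − J ΔC‖²_{Γe⁻¹} + λ ‖∇(ΔC)‖²_{Γx⁻¹}`

  with first-order Tikhonov (spatial-gradient) regularization and
  `Γx⁻¹ = diag(C_b)⁻²` *sphering* by background concentrations
  (56 / 24 / 12.8 µM for HbO2 / HHb / oxCCO), so the penalty acts equally
  on all chromophores. The augmented system `[J S; √λ L]` is solved with
  LSQR (≤ 50 iterations, tolerance 1e-5, λ = 1e-4 by default, with an
  L-curve selector included).

- **Residual analysis**: reconstructed images are back-projected to
  channel space; the difference between the residuals of the
  two-chromophore (HbO2+HHb) and three-chromophore (+oxCCO) models
  isolates the spectral structure only the oxCCO component explains — on
  synthetic data with a genuine oxCCO activation it reproduces the oxCCO
  difference-spectrum shape with a broad peak near 810 nm in the channels
  over the activation, and is near zero elsewhere.

The packaged extinction, DPF and tissue-optics tables are smooth synthetic
stand-ins anchored to widely cited literature values (see the CSV headers
in `src/ccodot/data/`); all quantitative tests are forward/inverse
self-consistent.

## Worked example

Simulate the default experiment (three-layer head slab, 4 sources × 8
detectors = 32 channels, focal activation blob of radius 15 mm at the
cortical surface with ΔHbO2 +1.0 µM, ΔHHb −0.3 µM, ΔoxCCO +0.1 µM,
noiseless), preprocess, fit channel concentrations and reconstruct the
20 s frame:

```python
import numpy as np
from ccodot import (ActivationBlob, NoiseModel, ReconstructionConfig,
                    assemble, compute_jacobians, default_phantom,
                    default_wavelengths, extinction_matrix, load_dpf,
                    simulate_experiment, ucln_fit, reconstruct,
                    intensity_to_attenuation, bandpass, block_average)
from ccodot.forward_model import coarsen_grid, project_jacobian

geometry, props, array = default_phantom()
wl = default_wavelengths()
jacobians = compute_jacobians(geometry, props, array, wl)

sim = simulate_experiment(geometry, props, array, ActivationBlob(),
                          wavelengths=wl, noise=NoiseModel(sd_od=0.0),
                          jacobians=jacobians)
dA = block_average(bandpass(intensity_to_attenuation(sim.intensities)),
                   sim.paradigm)

E = extinction_matrix(["HbO2", "HHb", "oxCCO"], wl)
conc = ucln_fit(dA, E, array.channel_distances(), load_dpf(),
                chromophores=["HbO2", "HHb", "oxCCO"])
ch = int(np.argmax(conc.data[:, 0, 20]))
print(f"strongest channel {ch}: "
      f"dHbO2={conc.data[ch, 0, 20]:+.4f} uM, "
      f"dHHb={conc.data[ch, 1, 20]:+.4f} uM, "
      f"doxCCO={conc.data[ch, 2, 20]:+.4f} uM at 20 s")

grid = coarsen_grid(jacobians[0].grid, 3.0)
system = assemble([project_jacobian(j, grid) for j in jacobians], E,
                  ["HbO2", "HHb", "oxCCO"])
img = reconstruct(dA.data[:, :, 20], system, ReconstructionConfig(),
                  time_s=20.0)
peak = np.unravel_index(np.argmax(img["HbO2"]), grid.shape)
print(f"image grid {grid.shape}, LSQR iterations {img.meta['iterations']}")
print(f"dHbO2 peak {img['HbO2'].max():.4f} uM at voxel center "
      f"{np.round(grid.centers().reshape(*grid.shape, 3)[peak], 1)} mm")
```

prints

```
strongest channel 8: dHbO2=+0.0009 uM, dHHb=-0.0009 uM, doxCCO=+0.0008 uM at 20 s
image grid (36, 22, 14), LSQR iterations 50
dHbO2 peak 0.0207 uM at voxel center [40.5 31.5  7.5] mm
```

The strongest channel shows the expected activation signature (HbO2 up,
HHb down, oxCCO up). The channel-space magnitudes are far below the focal
1 µM truth because the modified Beer–Lambert fit divides by the *whole*
pathlength while the change occupies a small cortical volume
(partial-volume dilution); the image peak is likewise amplitude-damped by
regularization. The reconstruction localizes the activation exactly in the
lateral plane (40.5, 31.5 vs true 39, 31.5 mm) but superficially in depth
— the expected behavior of smoothness-regularized DOT with a two-distance
array (see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
ccodot pipeline --seed 1 --out run1    # simulate ... residuals, manifest.json
ccodot simulate --seed 1 --out run1    # or stage by stage
```

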