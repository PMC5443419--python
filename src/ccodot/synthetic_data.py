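"""Synthetic phantoms, optode arrays and broadband datasets with ground truth.

The generator emulates a broadband functional acquisition over visual
cortex: 4 sources and 14 detector slots in three rows, 8 nearest-detector
channels per source (32 channels), 1 Hz sampling, a 20 s stimulation /
20 s rest block design repeated over 10 epochs, and a focal activation
blob in the brain layer modulating HbO2 (+), HHb (−) and oxCCO (+) with a
trapezoidal time course.  Channel attenuation changes are produced through
the diffusion-model Jacobians (linearized forward model), optionally on a
refined grid to avoid the inverse crime, then wrapped in positive
intensities about a modeled baseline so the full preprocessing chain can
be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import (DiffusionSolver, Geometry, OptodeArray,
                            WavelengthJacobian, compute_jacobian, layered_slab,
                            load_tissue_optics)
from .preprocess import IntensityTimeSeries, Paradigm
from .multispectral_inversion import ConcentrationImage
from .spectra import extinction_matrix

__all__ = [
    "ActivationBlob",
    "NoiseModel",
    "SimulationResult",
    "make_array",
    "default_phantom",
    "default_wavelengths",
    "compute_jacobians",
    "simulate_experiment",
]

DEFAULT_AMPLITUDES_UM = {"HbO2": 1.0, "HHb": -0.3, "oxCCO": 0.1}


def default_wavelengths() -> np.ndarray:
    """The 17-wavelength reconstruction grid, 740–900 nm in 10 nm steps."""
    return np.arange(740.0, 901.0, 10.0)


@dataclass
class ActivationBlob:
    """Focal activation: a smooth spherical concentration-change pattern.

    The spatial profile is a raised cosine, cos²(π r / 2R) inside radius R,
    restricted to brain-labeled voxels.  Peak amplitudes default to
    +1.0 µM HbO2, −0.3 µM HHb and +0.1 µM oxCCO — a functional-activation
    scale with the oxCCO change an order of magnitude below hemoglobin.
    The temporal profile is trapezoidal: linear rise over ``rise_s``,
    plateau until stimulus end, linear fall over ``fall_s``.
    """

    center_mm: tuple = (39.0, 31.5, 18.0)
    radius_mm: float = 15.0
    amplitudes_uM: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES_UM))
    rise_s: float = 5.0
    fall_s: float = 10.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("blob radius must be positive")

    @property
    def chromophores(self) -> list:
        return list(self.amplitudes_uM)

    def spatial_pattern(self, geometry: Geometry,
                        brain_tissue: str = "brain") -> np.ndarray:
        """Unit-peak pattern per voxel, masked to the brain layer."""
        centers = geometry.grid.centers()
        r = np.linalg.norm(centers - np.asarray(self.center_mm), axis=1)
        w = np.where(r < self.radius_mm,
                     np.cos(np.pi * r / (2.0 * self.radius_mm)) ** 2, 0.0)
        brain = geometry.mask(brain_tissue).ravel()
        c_idx = int(np.argmin(np.linalg.norm(
            centers - np.asarray(self.center_mm), axis=1)))
        if not brain[c_idx]:
            raise ValueError("activation blob center is not inside brain tissue")
        return w * brain

    def temporal_profile(self, paradigm: Paradigm, times_s) -> np.ndarray:
        """Trapezoidal activation time course g(t) in [0, 1]."""
        t = np.asarray(times_s, dtype=float)
        g = np.zeros_like(t)
        for onset in paradigm.onsets_s:
            rel = t - onset
            rise = (rel >= 0) & (rel < self.rise_s)
            plateau = (rel >= self.rise_s) & (rel < paradigm.stim_duration_s)
            fall = (rel >= paradigm.stim_duration_s) & \
                   (rel < paradigm.stim_duration_s + self.fall_s)
            g[rise] = np.maximum(g[rise], rel[rise] / self.rise_s)
            g[plateau] = 1.0
            g[fall] = np.maximum(
                g[fall], 1.0 - (rel[fall] - paradigm.stim_duration_s) / self.fall_s)
        return g

    def truth_image(self, geometry: Geometry, time_scale: float = 1.0,
                    chromophores=None, time_s=None) -> ConcentrationImage:
        """Ground-truth concentration image at a given activation level."""
        chromophores = list(chromophores or self.chromophores)
        pattern = self.spatial_pattern(geometry)
        data = np.stack([
            self.amplitudes_uM.get(c, 0.0) * time_scale
            * pattern.reshape(geometry.shape)
            for c in chromophores
        ])
        return ConcentrationImage(data, chromophores, geometry.grid,
                                  time_s=time_s)


@dataclass
class NoiseModel:
    """Seeded additive Gaussian attenuation noise (OD)."""

    sd_od: float = 5e-4
    per_wavelength_scale: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sd_od < 0:
            raise ValueError("noise sd must be non-negative")

    def sample(self, shape, n_wavelengths_axis: int = 1) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noise = rng.standard_normal(shape) * self.sd_od
        if self.per_wavelength_scale is not None:
            scale = np.asarray(self.per_wavelength_scale, dtype=float)
            sh = [1] * len(shape)
            sh[n_wavelengths_axis] = scale.size
            noise = noise * scale.reshape(sh)
        return noise


def make_array(pitch_mm: float = 15.0, row_sep_mm: float = 10.0,
               center_xy=(54.0, 31.5), surface_z: float = 0.0,
               n_sources: int = 4, n_detectors_per_row: int = 7,
               detectors_per_source: int = 8, source_sigma: float = 2.0,
               geometry: Geometry | None = None) -> OptodeArray:
    """Three-row optode layout: sources in a middle row, detectors above/below.

    Sources sit in the central row (staggered half a pitch relative to the
    detector columns); two detector rows of ``n_detectors_per_row`` slots
    flank them at ``row_sep_mm``.  Each source is paired with its
    ``detectors_per_source`` nearest detectors, giving the default
    4 × 8 = 32 channels with two distinct source–detector distances
    (overlapping, multidistance coverage).
    """
    cx, cy = center_xy
    det_x = cx + (np.arange(n_detectors_per_row)
                  - (n_detectors_per_row - 1) / 2.0) * pitch_mm
    src_x = cx + (np.arange(n_sources) - (n_sources - 1) / 2.0) * pitch_mm
    sources = np.column_stack([
        src_x, np.full(n_sources, cy), np.full(n_sources, surface_z)])
    det_top = np.column_stack([
        det_x, np.full(det_x.size, cy - row_sep_mm),
        np.full(det_x.size, surface_z)])
    det_bot = np.column_stack([
        det_x, np.full(det_x.size, cy + row_sep_mm),
        np.full(det_x.size, surface_z)])
    detectors = np.vstack([det_top, det_bot])
    if geometry is not None:
        g = geometry.grid
        lo = np.asarray(g.origin)
        hi = lo + g.extent
        pts = np.vstack([sources, detectors])
        if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
            raise ValueError("array footprint exceeds the domain")
    channels = []
    for si, s in enumerate(sources):
        d = np.linalg.norm(detectors - s, axis=1)
        nearest = np.argsort(d, kind="stable")[:detectors_per_source]
        channels += [(si, int(di)) for di in sorted(nearest)]
    return OptodeArray(sources, detectors, channels, source_sigma=source_sigma)


def default_phantom(spacing: float = 2.0):
    """Default three-layer slab phantom with the standard array on top.

    Returns (geometry, optical properties, optode array).  The domain is
    108 × 63 × 42 mm so the 90-mm array footprint fits with margin;
    layers are scalp+skull 12 mm, CSF 2 mm, brain below.
    """
    geometry = layered_slab(extent_mm=(108.0, 63.0, 42.0), spacing=spacing)
    props = load_tissue_optics()
    array = make_array(geometry=geometry)
    return geometry, props, array


def compute_jacobians(geometry, props, array, wavelengths,
                      boundary: str = "robin") -> list[WavelengthJacobian]:
    """One sensitivity matrix per wavelength (shared factorization per λ)."""
    jacs = []
    for wl in np.asarray(wavelengths, dtype=float):
        solver = DiffusionSolver(geometry, props, wl, boundary=boundary)
        jacs.append(compute_jacobian(geometry, props, array, wl, solver=solver))
    return jacs


@dataclass
class SimulationResult:
    """Simulated dataset plus everything needed to score a reconstruction."""

    intensities: IntensityTimeSeries
    attenuation_true: np.ndarray      # (channel, wavelength, time), OD, no noise
    wavelengths_nm: np.ndarray
    paradigm: Paradigm
    blob: ActivationBlob
    geometry: Geometry
    temporal_profile: np.ndarray      # g(t) over the full recording
    channel_signature: np.ndarray     # (channel, wavelength) ΔA at g = 1

    def truth_at(self, time_scale: float = 1.0, chromophores=None,
                 time_s=None) -> ConcentrationImage:
        return self.blob.truth_image(self.geometry, time_scale, chromophores,
                                     time_s=time_s)


def simulate_experiment(geometry, props, array, blob: ActivationBlob,
                        paradigm: Paradigm | None = None,
                        wavelengths=None, noise: NoiseModel | None = None,
                        spectra=None, jacobians=None,
                        sample_rate: float = 1.0, duration_s: float | None = None,
                        I0: float = 1e5) -> SimulationResult:
    """Simulate a broadband block-design experiment with known ground truth.

    The activation blob's concentration changes are converted to Δμa(λ)
    through the extinction matrix and to channel attenuation changes with
    the wavelength Jacobians (linearized forward model — pass ``jacobians``
    computed on a refined geometry for inverse-crime control).  Seeded
    Gaussian noise is added in attenuation space, and the result is
    expressed as positive intensities about the modeled channel baseline
    I0 · y₀ so that preprocessing runs on realistic raw data.
    """
    if paradigm is None:
        paradigm = Paradigm.block_design()
    if wavelengths is None:
        wavelengths = default_wavelengths()
    wavelengths = np.asarray(wavelengths, dtype=float)
    if noise is None:
        noise = NoiseModel()
    chroms = blob.chromophores
    E = extinction_matrix(chroms, wavelengths, spectra)  # (n_wl, n_chrom)
    if jacobians is None:
        jacobians = compute_jacobians(geometry, props, array, wavelengths)
    if len(jacobians) != wavelengths.size:
        raise ValueError("need one Jacobian per wavelength")
    if duration_s is None:
        duration_s = paradigm.onsets_s[-1] + paradigm.epoch_duration_s
    times = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    if paradigm.onsets_s[-1] + paradigm.epoch_duration_s > duration_s + 1e-9:
        raise ValueError("paradigm does not fit the simulated duration")

    sim_geometry = jacobians[0].grid
    pattern = blob.spatial_pattern(
        _geometry_for_grid(geometry, sim_geometry))
    amps = np.array([blob.amplitudes_uM[c] for c in chroms])
    dmua = np.outer(E @ amps, pattern)  # (n_wl, n_vox) at g = 1
    sig = np.stack([jac.matrix @ dmua[w]
                    for w, jac in enumerate(jacobians)])  # (n_wl, n_ch)
    signature = sig.T  # (channel, wavelength)
    g = blob.temporal_profile(paradigm, times)
    dA_true = signature[:, :, None] * g[None, None, :]
    dA = dA_true + noise.sample(dA_true.shape, n_wavelengths_axis=1)

    if jacobians[0].baseline is not None:
        y0 = np.stack([jac.baseline for jac in jacobians]).T  # (ch, wl)
    else:
        y0 = np.ones(dA.shape[:2])
    intensities = I0 * y0[:, :, None] * 10.0 ** (-dA)
    its = IntensityTimeSeries(intensities, wavelengths, sample_rate)
    return SimulationResult(its, dA_true, wavelengths, paradigm, blob,
                            geometry, g, signature)


def _geometry_for_grid(geometry: Geometry, grid) -> Geometry:
    """Geometry matching ``grid`` (refined copy when the Jacobians are finer)."""
    if grid.shape == geometry.grid.shape:
        return geometry
    factor = geometry.grid.spacing / grid.spacing
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("Jacobian grid is not an integer refinement")
    return geometry.refine(int(round(factor)))
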