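"""Back-projection residuals and the two- vs three-chromophore comparison.

After reconstruction, applying the multispectral operator to the image
predicts the channel attenuation changes the image explains.  The residual
r = ΔA_measured − ΔA_predicted is computed per channel and wavelength, in
reconstruction voxel space (before any surface mapping).  If a genuine
oxCCO signal is present, the residual of the two-chromophore model retains
spectral structure the three-chromophore model absorbs, so the difference
r₂(λ) − r₃(λ) in channels over the activation approximates the shape of the
oxCCO difference spectrum, while in distant channels it is near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multispectral_inversion import ConcentrationImage, MultispectralSystem

__all__ = [
    "ResidualSpectrum",
    "back_project",
    "residual_difference",
    "spectrum_similarity",
]


@dataclass
class ResidualSpectrum:
    """Per-channel, per-wavelength residual attenuation (OD)."""

    data: np.ndarray  # (n_channels, n_wavelengths)
    wavelengths_nm: np.ndarray
    model: str  # "2-chrom" | "3-chrom" | "difference"
    time_s: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.wavelengths_nm.size:
            raise ValueError("residual shape must be (n_channels, n_wavelengths)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("residuals must be finite")


def back_project(dC: ConcentrationImage,
                 system: MultispectralSystem) -> np.ndarray:
    """Predicted attenuation changes (channel × wavelength) for an image."""
    if list(dC.chromophores) != list(system.chromophores):
        raise ValueError(
            f"chromophore mismatch: image {dC.chromophores} vs "
            f"system {system.chromophores}"
        )
    return system.unstack(system.matvec(dC.flat()))


def compute_residual(dA_measured: np.ndarray, dC: ConcentrationImage,
                     system: MultispectralSystem,
                     time_s: float | None = None) -> ResidualSpectrum:
    """Residual r = measured − back-projected attenuation, per channel/λ."""
    dA_measured = np.asarray(dA_measured, dtype=float)
    pred = back_project(dC, system)
    tag = f"{system.n_chromophores}-chrom"
    return ResidualSpectrum(dA_measured - pred, system.wavelengths_nm, tag,
                            time_s=time_s)


def residual_difference(dA_measured, dC3: ConcentrationImage,
                        dC2: ConcentrationImage,
                        system3: MultispectralSystem,
                        system2: MultispectralSystem,
                        time_s: float = 20.0) -> ResidualSpectrum:
    """Spectral structure the two-chromophore model fails to explain.

    Returns r₂(λ) − r₃(λ) per channel, where r_k is the residual of the
    k-chromophore reconstruction of the same measured frame (typically the
    frame at the activation peak, 20 s after stimulus onset).
    """
    if (dC3.time_s is not None and dC2.time_s is not None
            and dC3.time_s != dC2.time_s):
        raise ValueError(
            f"reconstructions are from different frames "
            f"({dC3.time_s} s vs {dC2.time_s} s)"
        )
    if not np.array_equal(system3.wavelengths_nm, system2.wavelengths_nm):
        raise ValueError("systems use different wavelength grids")
    r3 = compute_residual(dA_measured, dC3, system3, time_s)
    r2 = compute_residual(dA_measured, dC2, system2, time_s)
    return ResidualSpectrum(r2.data - r3.data, system3.wavelengths_nm,
                            "difference", time_s=time_s)


def spectrum_similarity(diff_spectrum: np.ndarray, reference: np.ndarray,
                        wavelengths_nm: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a reference spectrum and the peak wavelength.

    The peak wavelength is the argmax of the difference spectrum after a
    3-point moving-average smoothing (edges keep shorter windows).
    """
    d = np.asarray(diff_spectrum, dtype=float)
    ref = np.asarray(reference, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if d.shape != ref.shape or d.shape != wl.shape:
        raise ValueError("spectra must share one wavelength grid")
    if np.ptp(d) == 0 or np.ptp(ref) == 0:
        raise ValueError("correlation undefined for a constant spectrum")
    r = float(np.corrcoef(d, ref)[0, 1])
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(d, kernel, mode="same")
    # renormalize the edge samples (window shorter than 3)
    norm = np.convolve(np.ones_like(d), kernel, mode="same")
    smoothed = smoothed / norm
    return r, float(wl[int(np.argmax(smoothed))])
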