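"""Channel-space multiwavelength spectroscopy (modified Beer–Lambert fitting).

Per channel and time point the attenuation change across wavelengths is
fitted by least squares to

    ΔA(λ) = Σ_c ε_c(λ) · ΔC_c · d · DPF(λ)

with d the source–detector distance (mm), DPF the differential pathlength
factor and ε the specific absorption coefficients (µM⁻¹·mm⁻¹), giving
concentration changes ΔC in µM.  This is the UCLn-style fit used as the
channel-space baseline against reconstructed images; it supports both the
two-chromophore (HbO2, HHb) and three-chromophore (+oxCCO) models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import DPFModel, dpf_at

__all__ = ["ChannelConcentrationSeries", "ucln_fit", "write_concentration_csv"]

_COND_LIMIT = 1e8


@dataclass
class ChannelConcentrationSeries:
    """Channel × chromophore × time concentration changes (µM)."""

    data: np.ndarray
    chromophores: list
    channel_ids: list
    sample_rate: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channel, chromophore, time)")
        if self.data.shape[1] != len(self.chromophores):
            raise ValueError("chromophore axis mismatch")
        if self.data.shape[1] not in (2, 3):
            raise ValueError("chromophore axis must have length 2 or 3")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("concentrations must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.data.shape[2]) / self.sample_rate


def ucln_fit(dA, E, distances_mm, dpf: DPFModel,
             chromophores=None) -> ChannelConcentrationSeries:
    """Least-squares chromophore fit of channel attenuation spectra.

    Parameters
    ----------
    dA
        :class:`~ccodot.preprocess.AttenuationSeries` (channel × wavelength
        × time, OD).
    E
        Extinction matrix (n_wavelengths × n_chromophores, µM⁻¹·mm⁻¹);
        rows must correspond to ``dA.wavelengths_nm``.
    distances_mm
        Per-channel source–detector distance (mm).
    dpf
        DPF model evaluated at the series wavelengths.
    chromophores
        Labels for the output axis (defaults to column indices).

    Notes
    -----
    Wavelengths are weighted uniformly; the solution per channel/time is
    ``pinv(E) @ (ΔA(λ) / (d · DPF(λ)))``.
    """
    E = np.asarray(E, dtype=float)
    n_wl, n_chrom = E.shape
    if dA.wavelengths_nm.size != n_wl:
        raise ValueError(
            f"wavelength mismatch: series has {dA.wavelengths_nm.size}, "
            f"extinction matrix has {n_wl} rows"
        )
    if n_wl < n_chrom:
        raise ValueError("need at least as many wavelengths as chromophores")
    d = np.asarray(distances_mm, dtype=float)
    if d.shape != (dA.data.shape[0],) or np.any(d <= 0):
        raise ValueError("distances must be positive, one per channel")
    if np.linalg.cond(E) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "extinction matrix is rank deficient or severely ill conditioned "
            "(duplicated chromophore?)"
        )
    pl = dpf_at(dA.wavelengths_nm, dpf)  # dimensionless, per wavelength
    P = np.linalg.pinv(E)  # (n_chrom, n_wl)
    # y[ch, wl, t] = dA / (d_ch * DPF(wl));  dC[ch, c, t] = P @ y[ch]
    y = dA.data / (d[:, None, None] * pl[None, :, None])
    dC = np.einsum("cw,nwt->nct", P, y)
    if chromophores is None:
        chromophores = [f"chrom{i}" for i in range(n_chrom)]
    return ChannelConcentrationSeries(dC, list(chromophores), list(dA.channel_ids),
                                      sample_rate=dA.sample_rate)


def write_concentration_csv(series: ChannelConcentrationSeries, path) -> None:
    ch, nc, nt = series.data.shape
    times = series.times_s
    pd.DataFrame({
        "channel": np.repeat(series.channel_ids, nc * nt),
        "chromophore": np.tile(np.repeat(series.chromophores, nt), ch),
        "time_s": np.tile(times, ch * nc),
        "delta_conc_uM": series.data.ravel(),
    }).to_csv(path, index=False)
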