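"""Chromophore extinction spectra and differential pathlength factor (DPF) models.

Canonical internal units are µM⁻¹·mm⁻¹ for specific absorption coefficients;
the packaged two-column CSV tables are stored in the conventional
mM⁻¹·cm⁻¹ and converted on load (1 mM⁻¹·cm⁻¹ = 1e-4 µM⁻¹·mm⁻¹).

The oxCCO entry is the *oxidized-minus-reduced* difference spectrum: it is
the quantity that multiplies Δ[oxCCO] (a redox-state change), not an
absolute extinction of a single species.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreSpectrum",
    "DPFModel",
    "load_spectrum",
    "load_dpf",
    "constant_dpf",
    "default_spectra",
    "extinction_matrix",
    "dpf_at",
    "MM_CM_TO_UM_MM",
]

#: conversion factor from mM⁻¹·cm⁻¹ to µM⁻¹·mm⁻¹
MM_CM_TO_UM_MM = 1e-4

CHROMOPHORES = ("HbO2", "HHb", "oxCCO")

_PACKAGED = {
    "HbO2": "extinction_hbo2_synthetic.csv",
    "HHb": "extinction_hhb_synthetic.csv",
    "oxCCO": "extinction_oxcco_diff_synthetic.csv",
}


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Tabulated specific absorption coefficient of one chromophore.

    Parameters
    ----------
    chromophore
        Identifier, one of ``HbO2``, ``HHb``, ``oxCCO``.
    wavelengths_nm
        Strictly increasing wavelength grid (nm).
    epsilon
        Specific absorption coefficient in µM⁻¹·mm⁻¹ at each wavelength.
        For oxCCO this is the oxidized-minus-reduced difference spectrum.
    """

    chromophore: str
    wavelengths_nm: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "epsilon", eps)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be a strictly increasing 1-d grid")
        if eps.shape != wl.shape:
            raise ValueError("epsilon and wavelengths shapes differ")
        if not np.all(np.isfinite(eps)) or np.any(eps < 0):
            raise ValueError(f"{self.chromophore}: epsilon must be finite and >= 0")

    def at(self, wavelengths_nm) -> np.ndarray:
        """Linearly interpolate epsilon onto ``wavelengths_nm`` (µM⁻¹·mm⁻¹)."""
        w = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        bad = (w < lo) | (w > hi)
        if np.any(bad):
            raise ValueError(
                f"wavelength {w[bad][0]:g} nm outside tabulated range "
                f"[{lo:g}, {hi:g}] nm for chromophore {self.chromophore}"
            )
        return np.interp(w, self.wavelengths_nm, self.epsilon)


@dataclass(frozen=True)
class DPFModel:
    """Wavelength dependence of the differential pathlength factor."""

    wavelengths_nm: np.ndarray
    dpf: np.ndarray
    name: str = "dpf"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        d = np.asarray(self.dpf, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "dpf", d)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("DPF wavelengths must be strictly increasing")
        if d.shape != wl.shape or not np.all(d > 0):
            raise ValueError("DPF values must be positive and match wavelengths")

    def at(self, wavelengths_nm) -> np.ndarray:
        return dpf_at(wavelengths_nm, self)


def _read_two_column(text: str) -> tuple[np.ndarray, np.ndarray, str]:
    header = [ln for ln in text.splitlines() if ln.startswith("#")]
    units = ""
    for ln in header:
        if "units:" in ln:
            units = ln.split("units:", 1)[1].strip()
    df = pd.read_csv(io.StringIO(text), comment="#")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), units


def load_spectrum(chromophore: str, path=None) -> ChromophoreSpectrum:
    """Load a chromophore spectrum from ``path`` or the packaged table.

    CSV format: optional ``# units:`` header, then (wavelength_nm, value)
    rows.  Values in mM⁻¹·cm⁻¹ are converted to the canonical µM⁻¹·mm⁻¹.
    """
    if path is None:
        if chromophore not in _PACKAGED:
            raise KeyError(
                f"unknown chromophore {chromophore!r}; expected one of {CHROMOPHORES}"
            )
        text = (
            resources.files("ccodot") / "data" / _PACKAGED[chromophore]
        ).read_text()
    else:
        text = open(path).read()
    wl, val, units = _read_two_column(text)
    units_key = units.lower().replace(" ", "")
    if units_key.startswith("mm^-1cm^-1") or units_key == "":
        val = val * MM_CM_TO_UM_MM
    elif not units_key.startswith("um^-1mm^-1"):
        raise ValueError(f"unrecognised spectrum units {units!r}")
    return ChromophoreSpectrum(chromophore, wl, val)


def load_dpf(path=None) -> DPFModel:
    """Load a DPF wavelength-dependence table (packaged adult-head default)."""
    if path is None:
        text = (
            resources.files("ccodot") / "data" / "dpf_adult_head_synthetic.csv"
        ).read_text()
        name = "adult_head_synthetic"
    else:
        text = open(path).read()
        name = str(path)
    wl, val, _ = _read_two_column(text)
    return DPFModel(wl, val, name=name)


def constant_dpf(value: float = 6.0, lo: float = 700.0, hi: float = 1000.0) -> DPFModel:
    """Constant (wavelength-independent) DPF model.

    With a constant DPF, channel-space concentration changes are scaled
    uniformly across wavelengths; spectral shapes are unaffected but the
    absolute µM scale inherits any error in ``value``.
    """
    if value <= 0:
        raise ValueError("DPF must be positive")
    return DPFModel(np.array([lo, hi]), np.array([value, value]), name=f"constant({value})")


def default_spectra() -> dict[str, ChromophoreSpectrum]:
    """The packaged spectra for HbO2, HHb and oxCCO keyed by identifier."""
    return {c: load_spectrum(c) for c in CHROMOPHORES}


def extinction_matrix(chromophores, wavelengths_nm, spectra=None) -> np.ndarray:
    """Specific-absorption matrix E with E[i, j] = ε of chromophore j at λ_i.

    Parameters
    ----------
    chromophores
        Requested chromophore identifiers; column order follows this order.
    wavelengths_nm
        Requested wavelengths (nm); must lie inside every chromophore's
        tabulated range.
    spectra
        Mapping identifier → :class:`ChromophoreSpectrum`.  Defaults to the
        packaged tables.

    Returns
    -------
    ndarray, shape (n_wavelengths, n_chromophores), units µM⁻¹·mm⁻¹.
    """
    if spectra is None:
        spectra = default_spectra()
    cols = []
    for c in chromophores:
        if c not in spectra:
            raise KeyError(f"unknown chromophore {c!r}; available: {sorted(spectra)}")
        cols.append(spectra[c].at(wavelengths_nm))
    return np.column_stack(cols)


def dpf_at(wavelengths_nm, model: DPFModel) -> np.ndarray:
    """Interpolated DPF values at ``wavelengths_nm`` (all > 0)."""
    w = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    lo, hi = model.wavelengths_nm[0], model.wavelengths_nm[-1]
    bad = (w < lo) | (w > hi)
    if np.any(bad):
        raise ValueError(
            f"wavelength {w[bad][0]:g} nm outside DPF model range [{lo:g}, {hi:g}] nm"
        )
    return np.interp(w, model.wavelengths_nm, model.dpf)
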