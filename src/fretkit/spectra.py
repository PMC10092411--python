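"""Wavelength-gridded spectra: container, CSV I/O, and simple constructors.

A :class:`Spectrum` holds either a molar-absorptivity band (M^-1 cm^-1) or an
emission band in arbitrary units, on a strictly increasing wavelength grid in
nm.  The on-disk dialect is a two-column CSV with a mandatory header
``wavelength_nm,value``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

SpectrumKind = Literal["absorption", "emission"]


@dataclass(frozen=True)
class Spectrum:
    """A non-negative spectral band on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelength grid in nm, strictly increasing, length >= 2.
    values : array-like
        Molar absorptivity (M^-1 cm^-1) for ``kind="absorption"``,
        arbitrary-unit intensity for ``kind="emission"``.  Must be >= 0.
    kind : {"absorption", "emission"}
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "absorption"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing (no duplicates)")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if self.kind not in ("absorption", "emission"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    # -- evaluation ---------------------------------------------------------
    def __call__(self, wl: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the support."""
        return np.interp(np.asarray(wl, dtype=float), self.wavelengths, self.values,
                         left=0.0, right=0.0)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def area(self) -> float:
        """Trapezoidal integral of the band over its own grid."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * factor, self.kind)

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_csv(cls, path: str | Path, kind: SpectrumKind = "absorption") -> "Spectrum":
        df = pd.read_csv(path)
        if "wavelength_nm" not in df.columns or "value" not in df.columns:
            raise ValueError(
                f"{path}: expected header 'wavelength_nm,value', got {list(df.columns)}")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths, "value": self.values}).to_csv(
            path, index=False)


def gaussian_spectrum(center: float, fwhm: float, peak: float,
                      grid: np.ndarray, kind: SpectrumKind = "absorption") -> Spectrum:
    """Gaussian band with the given center (nm), FWHM (nm) and peak value.

    Used by the synthetic-data generator to emulate DCM-like bands
    (absorption maximum 457 nm, emission maximum 590 nm).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = peak * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, values, kind)


def z_epsilon_from_pss(eps_E: Spectrum, A_pss: Spectrum, alpha_Z: float,
                       c: float, l: float) -> Spectrum:
    """Reconstruct the (Z)-isomer absorptivity from a photostationary mixture.

    At the photostationary state a fraction ``alpha_Z`` of the chromophores is
    in the Z form, so the measured absorbance obeys Beer-Lambert additivity::

        A_PSS(l) = c*l * [(1 - alpha_Z) * eps_E(l) + alpha_Z * eps_Z(l)]

    which is inverted for ``eps_Z``.  Negative values (noise) are clipped at
    zero with a warning.

    Parameters
    ----------
    eps_E : Spectrum
        Pure E-isomer molar absorptivity.
    A_pss : Spectrum
        Measured photostationary absorbance (dimensionless), same kind of grid.
    alpha_Z : float
        Fraction of units converted to Z at the PSS, in (0, 1].
    c, l : float
        Total chromophore concentration (mol L^-1) and path length (cm).
    """
    if not 0.0 < alpha_Z <= 1.0:
        raise ValueError("alpha_Z must be in (0, 1]")
    if c <= 0 or l <= 0:
        raise ValueError("concentration and path length must be positive")
    grid = A_pss.wavelengths
    eps_mix = A_pss.values / (c * l)
    eps_Z = (eps_mix - (1.0 - alpha_Z) * eps_E(grid)) / alpha_Z
    if np.any(eps_Z < 0):
        warnings.warn("negative eps_Z values clipped to zero", stacklevel=2)
        eps_Z = np.clip(eps_Z, 0.0, None)
    return Spectrum(grid, eps_Z, "absorption")
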