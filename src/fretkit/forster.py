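"""Forster-theory core: overlap integral, Forster radius, orientation factor,
transfer efficiency, and steady-state anisotropy relations.

The transfer efficiency between a donor/acceptor pair separated by R_DA is

    E = 1 / (1 + (R_DA / R0)^6)

with the Forster radius R0 given by

    R0^6 = 9000 ln(10) kappa^2 Phi_D0 J / (128 pi^5 N_A n^4)

where J = Int FbarD(l) epsA(l) l^4 dl is the overlap of the area-normalized
donor emission with the acceptor molar absorptivity, kappa^2 the orientation
factor in [0, 4], Phi_D0 the donor quantum yield without transfer and n the
refractive index of the medium.  With J in nm^4 M^-1 cm^-1 the radius comes
out in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CM_TO_NM, FORSTER_PREFACTOR, NM4_TO_CM4
from .spectra import Spectrum

__all__ = [
    "ForsterPairParams",
    "PairGeometry",
    "overlap_integral",
    "forster_radius",
    "fret_efficiency",
    "kappa_squared_angles",
    "kappa_squared_vectors",
    "fundamental_anisotropy",
    "mixed_anisotropy",
]


@dataclass(frozen=True)
class ForsterPairParams:
    """Photophysical parameters of a donor/acceptor pair.

    ``kappa2`` may be a number (fixed orientation factor, e.g. the isotropic
    dynamic average 2/3) or the string ``"dynamic"`` meaning the per-frame
    orientation factor is used when evaluating trajectories.
    """

    J: float                     # nm^4 M^-1 cm^-1
    phiD0: float                 # donor quantum yield w/o transfer
    n: float                     # refractive index
    kappa2: float | str = "dynamic"

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("overlap integral J must be >= 0")
        if not 0.0 <= self.phiD0 <= 1.0:
            raise ValueError("phiD0 must be in [0, 1]")
        if self.n <= 1.0:
            raise ValueError("refractive index must exceed 1")
        if isinstance(self.kappa2, str):
            if self.kappa2 != "dynamic":
                raise ValueError("kappa2 policy must be a number or 'dynamic'")
        elif not 0.0 <= float(self.kappa2) <= 4.0:
            raise ValueError("kappa2 must be in [0, 4]")

    def R0(self, kappa2: float | np.ndarray | None = None) -> float | np.ndarray:
        """Forster radius in nm for the given (or fixed) orientation factor."""
        if kappa2 is None:
            if self.kappa2 == "dynamic":
                raise ValueError("dynamic-kappa2 params need an explicit kappa2")
            kappa2 = float(self.kappa2)
        return forster_radius(self.J, kappa2, self.phiD0, self.n)


@dataclass(frozen=True)
class PairGeometry:
    """Scalar geometry of one donor/acceptor pair configuration.

    Angles follow the standard convention: ``theta_D`` (``theta_A``) is the
    angle between the separation vector and the donor (acceptor) transition
    dipole; ``phi`` is the dihedral between the two planes each spanned by the
    separation vector and one dipole, right-handed about the separation axis.
    """

    R_DA: float          # nm
    theta_D: float       # rad, [0, pi]
    theta_A: float       # rad, [0, pi]
    phi: float           # rad, (-pi, pi]

    @property
    def kappa2(self) -> float:
        return float(kappa_squared_angles(self.theta_D, self.theta_A, self.phi))


def overlap_integral(donor_em: Spectrum, acceptor_abs: Spectrum) -> float:
    """Spectral overlap integral J in nm^4 M^-1 cm^-1.

    J = Int FbarD(l) epsA(l) l^4 dl with the donor emission area-normalized
    over its own support (Int FbarD dl = 1).  Trapezoidal quadrature on the
    union of the two grids restricted to the common window, with linear
    interpolation; disjoint supports give J = 0.
    """
    if donor_em.kind != "emission":
        raise ValueError("donor spectrum must be of kind 'emission'")
    if acceptor_abs.kind != "absorption":
        raise ValueError("acceptor spectrum must be of kind 'absorption'")
    lo = max(donor_em.support[0], acceptor_abs.support[0])
    hi = min(donor_em.support[1], acceptor_abs.support[1])
    if lo >= hi:
        return 0.0
    area = donor_em.area()
    if area <= 0:
        raise ValueError("donor emission has zero area; cannot normalize")
    grid = np.union1d(donor_em.wavelengths, acceptor_abs.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        return 0.0
    integrand = (donor_em(grid) / area) * acceptor_abs(grid) * grid**4
    return float(np.trapezoid(integrand, grid))


def forster_radius(J: float | np.ndarray, kappa2: float | np.ndarray,
                   phiD0: float, n: float) -> float | np.ndarray:
    """Forster radius R0 in nm from J (nm^4 M^-1 cm^-1), kappa^2, Phi_D0, n."""
    J = np.asarray(J, dtype=float)
    kappa2 = np.asarray(kappa2, dtype=float)
    if np.any(J < 0) or np.any(kappa2 < 0) or phiD0 < 0 or n <= 0:
        raise ValueError("J, kappa2, phiD0 must be >= 0 and n > 0")
    r0_cm6 = FORSTER_PREFACTOR * kappa2 * phiD0 / n**4 * (J * NM4_TO_CM4)
    r0_nm = r0_cm6 ** (1.0 / 6.0) * CM_TO_NM
    return float(r0_nm) if r0_nm.ndim == 0 else r0_nm


def fret_efficiency(R_DA: float | np.ndarray, R0: float | np.ndarray) -> float | np.ndarray:
    """Transfer efficiency E = 1 / (1 + (R_DA/R0)^6), elementwise.

    Limits: R0 = 0 gives E = 0 (no transfer channel); R_DA = 0 with R0 > 0
    gives E = 1 (contact limit).
    """
    R_DA = np.asarray(R_DA, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    if np.any(R_DA < 0) or np.any(R0 < 0):
        raise ValueError("distances must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio6 = np.where(R0 > 0, (R_DA / np.where(R0 > 0, R0, 1.0)) ** 6, np.inf)
    eff = 1.0 / (1.0 + ratio6)
    eff = np.where(R0 == 0, 0.0, eff)
    return float(eff) if eff.ndim == 0 else eff


def kappa_squared_angles(theta_D, theta_A, phi):
    """Orientation factor from spherical angles.

    kappa^2 = (sin(tD) sin(tA) cos(phi) - 2 cos(tD) cos(tA))^2, in [0, 4].
    """
    theta_D = np.asarray(theta_D, dtype=float)
    theta_A = np.asarray(theta_A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    kappa = (np.sin(theta_D) * np.sin(theta_A) * np.cos(phi)
             - 2.0 * np.cos(theta_D) * np.cos(theta_A))
    out = kappa**2
    return float(out) if out.ndim == 0 else out


def _angles_from_vectors(mu_D: np.ndarray, mu_A: np.ndarray,
                         R_vec: np.ndarray) -> tuple[float, float, float]:
    """Extract (theta_D, theta_A, phi) from dipoles and separation vector.

    phi is the signed dihedral between the (R, mu_D) and (R, mu_A) planes,
    right-handed about the unit separation vector.  When a dipole is parallel
    to R the dihedral is undefined; phi = 0 by convention (kappa^2 is then
    insensitive to phi).
    """
    r_hat = R_vec / np.linalg.norm(R_vec)
    d_hat = mu_D / np.linalg.norm(mu_D)
    a_hat = mu_A / np.linalg.norm(mu_A)
    cos_d = np.clip(d_hat @ r_hat, -1.0, 1.0)
    cos_a = np.clip(a_hat @ r_hat, -1.0, 1.0)
    theta_D = float(np.arccos(cos_d))
    theta_A = float(np.arccos(cos_a))
    # in-plane (perpendicular-to-R) components of the dipoles
    d_perp = d_hat - cos_d * r_hat
    a_perp = a_hat - cos_a * r_hat
    nd, na = np.linalg.norm(d_perp), np.linalg.norm(a_perp)
    if nd < 1e-12 or na < 1e-12:
        return theta_D, theta_A, 0.0
    d_perp /= nd
    a_perp /= na
    cos_phi = np.clip(d_perp @ a_perp, -1.0, 1.0)
    sin_phi = float(r_hat @ np.cross(d_perp, a_perp))
    return theta_D, theta_A, float(np.arctan2(sin_phi, cos_phi))


def kappa_squared_vectors(mu_D: np.ndarray, mu_A: np.ndarray,
                          R_vec: np.ndarray) -> tuple[float, PairGeometry]:
    """Orientation factor from dipole vectors and the separation vector.

    kappa = muD_hat . muA_hat - 3 (muD_hat . R_hat)(muA_hat . R_hat); the
    returned :class:`PairGeometry` carries the equivalent spherical angles,
    whose angle-route kappa^2 agrees with the vector route to ~1e-10.
    """
    mu_D = np.asarray(mu_D, dtype=float)
    mu_A = np.asarray(mu_A, dtype=float)
    R_vec = np.asarray(R_vec, dtype=float)
    for name, v in (("mu_D", mu_D), ("mu_A", mu_A), ("R_vec", R_vec)):
        if np.linalg.norm(v) <= 0:
            raise ValueError(f"{name} has zero length")
    r_norm = np.linalg.norm(R_vec)
    r_hat = R_vec / r_norm
    d_hat = mu_D / np.linalg.norm(mu_D)
    a_hat = mu_A / np.linalg.norm(mu_A)
    kappa = d_hat @ a_hat - 3.0 * (d_hat @ r_hat) * (a_hat @ r_hat)
    theta_D, theta_A, phi = _angles_from_vectors(mu_D, mu_A, R_vec)
    geom = PairGeometry(R_DA=float(r_norm), theta_D=theta_D, theta_A=theta_A, phi=phi)
    return float(kappa**2), geom


def fundamental_anisotropy(beta: float) -> float:
    """Fundamental anisotropy r0 = 0.4 (3 cos^2(beta) - 1) / 2.

    ``beta`` is the angle, in degrees, between the absorption and emission
    transition dipole moments.  beta = 0 gives the one-photon limit 0.4; the
    magic angle 54.7356 deg gives 0.
    """
    if not 0.0 <= beta <= 90.0:
        raise ValueError("beta must be in [0, 90] degrees")
    c = np.cos(np.deg2rad(beta))
    return float(0.4 * (3.0 * c * c - 1.0) / 2.0)


def mixed_anisotropy(r0: float, p_transfer: float, r_et: float = 0.016) -> float:
    """Steady-state anisotropy of a mixture of direct and post-hop emission.

    Homo-transfer between like chromophores depolarizes emission: photons
    emitted after at least one hop carry the low residual anisotropy ``r_et``
    (default 0.016, near-random post-hop orientation), so

        rbar = (1 - p_transfer) r0 + p_transfer r_et
    """
    if not 0.0 <= p_transfer <= 1.0:
        raise ValueError("p_transfer must be in [0, 1]")
    return float((1.0 - p_transfer) * r0 + p_transfer * r_et)
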