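"""Competitive photoisomerization and FRET in 1-3 chromophore systems.

Each chromophore unit is a clean two-state E/Z photoswitch: the emissive
E form and the dark Z form interconvert photochemically with quantum yields
Phi_EZ and Phi_ZE.  Within one molecule an excited E unit can hand its energy
to a neighbour before deciding its fate — homo-FRET to another E unit
(hopping) or hetero-FRET to a Z unit (quenching that nevertheless promotes
the Z->E back reaction).  The model has two layers:

1. *Per-photon*: an absorbing Markov chain over the units.  At each visited
   unit the excitation either transfers to a neighbour (probability from the
   pairwise FRET matrix), isomerizes the resident unit (remaining probability
   times the isomer's quantum yield), or decays.  The chain is solved exactly
   via the fundamental matrix (I - Q)^-1 R.
2. *Species level*: first-order kinetics over the 2^n isomer configurations.
   Unit u of a species is excited at a rate proportional to flux times its
   isomer's absorptivity at the irradiation wavelength; each excitation's
   fate maps the species to one with a single unit flipped.

Absorbance follows Beer-Lambert additivity over units (weak coupling).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .spectra import Spectrum

__all__ = ["KineticParams", "PhotoSystem", "AbsorbanceTrace", "excitation_fate",
           "build_rate_matrix", "simulate_irradiation", "pss_composition",
           "pss_ratio", "time_to_pss", "merge_symmetric"]

Configuration = tuple[str, ...]


def dcm_like_params(p_homo: float = 0.35, p_hetero: float = 0.35,
                    flux: float = 1e-4) -> "KineticParams":
    """DCM-like demo parameter set (documented defaults, not fitted).

    E-form band: Gaussian, max 457 nm, peak 48 700 M^-1 cm^-1 (monomer
    absorptivity); Z-form band blue-shifted (420 nm) and weaker, retaining
    appreciable absorptivity at 457-485 nm as the real Z isomer does.
    Quantum yields Phi_EZ = 0.05, Phi_ZE = 0.35 put the visible-light PSS in
    the E-rich regime characteristic of these photoswitches.
    """
    from .spectra import gaussian_spectrum
    grid = np.arange(300.0, 701.0, 1.0)
    eps_E = gaussian_spectrum(457.0, 90.0, 48700.0, grid)
    eps_Z = gaussian_spectrum(420.0, 100.0, 28000.0, grid)
    return KineticParams(eps_E=eps_E, eps_Z=eps_Z, phi_EZ=0.05, phi_ZE=0.35,
                         p_homo=p_homo, p_hetero=p_hetero, flux=flux)


@dataclass(frozen=True)
class KineticParams:
    """Photophysical constants of the chromophore units.

    ``p_homo``/``p_hetero`` are the per-excitation transfer probabilities from
    an excited E unit to an E (Z) neighbour; excited Z units do not transfer
    (the Z form is dark).  ``flux`` scales the excitation rate: the rate of
    exciting unit u at wavelength l is flux * eps_isomer(u)(l).
    """

    eps_E: Spectrum
    eps_Z: Spectrum
    phi_EZ: float            # E -> Z isomerization quantum yield
    phi_ZE: float            # Z -> E
    p_homo: float = 0.0
    p_hetero: float = 0.0
    flux: float = 1.0
    phi_F: float = 0.0       # emission yield (bookkeeping only)

    def __post_init__(self) -> None:
        for name in ("phi_EZ", "phi_ZE", "p_homo", "p_hetero", "phi_F"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.flux < 0:
            raise ValueError("flux must be >= 0")

    def epsilon(self, isomer: str, wavelength: float) -> float:
        spec = self.eps_E if isomer == "E" else self.eps_Z
        return float(spec(np.asarray(wavelength)))

    def phi_iso(self, isomer: str) -> float:
        return self.phi_EZ if isomer == "E" else self.phi_ZE

    def transfer_prob(self, donor: str, acceptor: str) -> float:
        if donor != "E":
            return 0.0
        return self.p_homo if acceptor == "E" else self.p_hetero


def _configurations(n_units: int) -> list[Configuration]:
    return [tuple(c) for c in itertools.product("EZ", repeat=n_units)]


def excitation_fate(configuration: Configuration, params: KineticParams,
                    initially_excited_unit: int) -> dict:
    """Fate distribution of one absorbed photon.

    Returns ``{"isomerize": {unit: prob, ...}, "decay": prob}``; the entries
    sum to 1 (fundamental-matrix solution of the absorbing chain over units).
    """
    n = len(configuration)
    if not 0 <= initially_excited_unit < n:
        raise ValueError("excited unit index out of range")
    Q = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            if u != v:
                Q[u, v] = params.transfer_prob(configuration[u], configuration[v])
        if Q[u].sum() > 1.0 + 1e-12:
            raise ValueError("per-unit transfer probabilities exceed 1")
    # absorbing outcomes per visited unit: isomerize there, or decay
    stay = 1.0 - Q.sum(axis=1)
    R = np.zeros((n, n + 1))
    for u in range(n):
        R[u, u] = stay[u] * params.phi_iso(configuration[u])
        R[u, n] = stay[u] * (1.0 - params.phi_iso(configuration[u]))
    B = np.linalg.solve(np.eye(n) - Q, R)
    probs = B[initially_excited_unit]
    if abs(probs.sum() - 1.0) > 1e-12:
        raise AssertionError("fate probabilities must sum to 1")
    return {"isomerize": {u: float(probs[u]) for u in range(n)},
            "decay": float(probs[n])}


@dataclass(frozen=True)
class PhotoSystem:
    """Species-level linear kinetics generator at one irradiation wavelength.

    ``generator`` is the 2^n x 2^n matrix G with dc/dt = G c over the
    configuration concentrations (columns sum to zero: molecules conserved).
    """

    n_units: int
    configurations: tuple[Configuration, ...]
    generator: np.ndarray
    wavelength: float
    params: KineticParams

    def index(self, configuration: Configuration) -> int:
        return self.configurations.index(tuple(configuration))

    def epsilon_species(self, wavelength: float) -> np.ndarray:
        """Per-species absorptivity: sum of unit absorptivities (additivity)."""
        return np.array([sum(self.params.epsilon(iso, wavelength) for iso in cfg)
                         for cfg in self.configurations])


def build_rate_matrix(n_units: int, params: KineticParams,
                      wavelength: float) -> PhotoSystem:
    """Assemble the first-order generator over isomer configurations."""
    if n_units not in (1, 2, 3):
        raise ValueError("n_units must be 1, 2 or 3")
    configs = _configurations(n_units)
    idx = {c: i for i, c in enumerate(configs)}
    G = np.zeros((len(configs), len(configs)))
    for c in configs:
        i = idx[c]
        for u in range(n_units):
            k_exc = params.flux * params.epsilon(c[u], wavelength)
            if k_exc == 0:
                continue
            fate = excitation_fate(c, params, u)
            for v, p_iso in fate["isomerize"].items():
                if p_iso == 0:
                    continue
                flipped = list(c)
                flipped[v] = "Z" if c[v] == "E" else "E"
                j = idx[tuple(flipped)]
                G[j, i] += k_exc * p_iso
                G[i, i] -= k_exc * p_iso
    return PhotoSystem(n_units, tuple(configs), G, float(wavelength), params)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """Absorbance at a probe wavelength along an irradiation schedule."""

    times: np.ndarray          # s
    absorbance: np.ndarray
    probe_wavelength: float
    path_length: float
    concentrations: np.ndarray  # (n_times, n_species), mol/L
    configurations: tuple[Configuration, ...]


def simulate_irradiation(initial: np.ndarray | dict, params: KineticParams,
                         schedule, probe_wavelength: float = 457.0,
                         path_length: float = 1.0, n_units: int | None = None,
                         points_per_segment: int = 200) -> AbsorbanceTrace:
    """Propagate the species kinetics through an irradiation schedule.

    ``schedule`` is a list of ``(wavelength, flux, duration)`` segments;
    ``initial`` is either a concentration vector over configurations (mol/L,
    in the itertools product order) or a ``{configuration: conc}`` dict.
    The linear ODE is solved exactly segment-wise with the matrix
    exponential.
    """
    if isinstance(initial, dict):
        keys = [tuple(k) for k in initial]
        n_units = len(keys[0])
        configs = _configurations(n_units)
        c0 = np.zeros(len(configs))
        for k, v in initial.items():
            c0[configs.index(tuple(k))] = v
    else:
        c0 = np.asarray(initial, dtype=float)
        if n_units is None:
            n_units = int(np.log2(len(c0)))
        configs = _configurations(n_units)
    if np.any(c0 < 0):
        raise ValueError("initial concentrations must be >= 0")
    times_all = [np.array([0.0])]
    concs_all = [c0[None, :]]
    t0 = 0.0
    c = c0.copy()
    system = None
    for wavelength, flux, duration in schedule:
        if duration <= 0:
            raise ValueError("segment durations must be positive")
        seg_params = KineticParams(params.eps_E, params.eps_Z, params.phi_EZ,
                                   params.phi_ZE, params.p_homo, params.p_hetero,
                                   flux, params.phi_F)
        system = build_rate_matrix(n_units, seg_params, wavelength)
        ts = np.linspace(0.0, duration, points_per_segment + 1)[1:]
        # one eigendecomposition-free exact propagation per output point
        step = ts[1] - ts[0] if len(ts) > 1 else ts[0]
        P = scipy.linalg.expm(system.generator * step)
        seg = np.empty((len(ts), len(c)))
        for i in range(len(ts)):
            c = P @ c
            seg[i] = c
        times_all.append(t0 + ts)
        concs_all.append(seg)
        t0 += duration
    times = np.concatenate(times_all)
    concs = np.concatenate(concs_all, axis=0)
    if np.any(concs < -1e-12 * max(c0.sum(), 1e-300)):
        raise RuntimeError("integrator produced negative concentrations")
    eps = (system.epsilon_species(probe_wavelength) if system is not None
           else PhotoSystem(n_units, tuple(configs), np.zeros((len(c0),) * 2),
                            probe_wavelength, params).epsilon_species(probe_wavelength))
    absorbance = concs @ eps * path_length
    return AbsorbanceTrace(times, absorbance, float(probe_wavelength),
                           float(path_length), concs, tuple(configs))


def pss_composition(system: PhotoSystem, total: float = 1.0) -> np.ndarray:
    """Stationary species distribution of the generator (null-space solve)."""
    ns = scipy.linalg.null_space(system.generator, rcond=1e-10)
    if ns.shape[1] == 0:
        raise ValueError("generator has no stationary state")
    if ns.shape[1] > 1:
        raise ValueError("non-unique stationary state (reducible generator); "
                         "report per reachable component instead")
    pss = np.abs(np.real(ns[:, 0]))
    return pss / pss.sum() * total


def pss_ratio(params: KineticParams, n_units: int, lambda_1: float,
              lambda_2: float, probe_wavelength: float = 457.0) -> float:
    """Ratio of photostationary absorbances A_PSS(l1)/A_PSS(l2) at the probe.

    Each PSS is the stationary composition under continuous irradiation at
    the given wavelength; absorbances follow unit additivity (concentration
    and path length cancel in the ratio).
    """
    ratios = []
    for wl in (lambda_1, lambda_2):
        system = build_rate_matrix(n_units, params, wl)
        pss = pss_composition(system)
        ratios.append(float(pss @ system.epsilon_species(probe_wavelength)))
    if ratios[1] == 0:
        raise ZeroDivisionError("reference PSS absorbance is zero")
    return ratios[0] / ratios[1]


def time_to_pss(trace: AbsorbanceTrace, tolerance: float = 0.05) -> float:
    """First time the absorbance settles within ``tolerance`` of its plateau.

    Measured against the total excursion |A(0) - A(inf)|; the trace must stay
    inside the band afterwards.  Returns NaN when the trace never converges
    (for instance under zero flux, where nothing evolves).
    """
    A = trace.absorbance
    A_inf = A[-1]
    excursion = abs(A[0] - A_inf)
    if excursion <= 0:
        return float("nan")
    inside = np.abs(A - A_inf) <= tolerance * excursion
    # last index where the trace is still outside the band
    outside = np.where(~inside)[0]
    if len(outside) == 0:
        return float(trace.times[0])
    first = outside[-1] + 1
    if first >= len(A):
        return float("nan")
    return float(trace.times[first])


def merge_symmetric(system: PhotoSystem, concentrations: np.ndarray) -> dict:
    """Report concentrations merged over symmetry-equivalent configurations.

    For identical linkers EZ and ZE are the same chemical species; merging is
    representational only (the full-configuration dynamics is unchanged).
    """
    merged: dict[tuple[str, ...], float] = {}
    for cfg, c in zip(system.configurations, concentrations):
        key = tuple(sorted(cfg))
        merged[key] = merged.get(key, 0.0) + float(c)
    return merged
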