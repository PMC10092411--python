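"""Ground-truth generator for metastable two-chromophore tether dynamics.

Real tethered chromophore pairs (e.g. two DCM dyes on a flexible dendritic
linker) interconvert between metastable conformations — unfolded, partially
folded, compactly folded — with distinct interchromophoric distance and
dipole-orientation statistics.  This module emits synthetic geometry
trajectories with a *known* hidden state path, emission distributions and
exchange rates, so every downstream estimator (FRET traces, MSMs, fluxes)
can be checked against planted truth.

The emission model is a hidden Markov chain: per frame the active state
draws R_DA from a log-normal (median nm, sigma in log-space) and the dipole
angles from reflected/wrapped Gaussians around state-specific means.  The
defaults mirror a 200 ns trajectory sampled every 5 ps (40 000 frames).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .forster import ForsterPairParams, forster_radius, fret_efficiency, kappa_squared_angles
from .spectra import Spectrum, gaussian_spectrum
from .trajectory import GeometryFrame, write_geometry_table

__all__ = ["StateSpec", "ScenarioSpec", "GroundTruth", "simulate_scenario",
           "theoretical_mean_efficiency", "preset_scenario", "write_fixture_bundle",
           "dcm_like_spectra", "PRESETS"]


@dataclass(frozen=True)
class StateSpec:
    """Emission distributions of one metastable conformational state."""

    name: str
    r_median: float        # nm, log-normal median of R_DA
    sigma_log: float       # log-space spread of R_DA
    theta_D: float         # mean donor dipole angle to R, rad
    theta_A: float         # mean acceptor dipole angle, rad
    phi: float             # mean dihedral, rad
    angular_sigma: float   # Gaussian spread of all three angles, rad

    def __post_init__(self) -> None:
        if self.r_median <= 0 or self.sigma_log < 0 or self.angular_sigma < 0:
            raise ValueError(f"invalid distribution parameters for state {self.name}")


@dataclass(frozen=True)
class ScenarioSpec:
    """States plus per-step jump probabilities of the hidden chain."""

    states: tuple[StateSpec, ...]
    transition_matrix: np.ndarray   # per-step, rows sum to 1
    dt: float = 5.0                 # ps per frame
    dominant_pathway: tuple[str, ...] | None = None
    #: correlation time (ps) of an optional OU process applied to the
    #: intra-state fluctuations; None (default) keeps emissions i.i.d. so
    #: closed-form oracles stay exact.  The OU recursion acts on the
    #: underlying standard-normal deviates and resets at state changes, so
    #: per-state marginal distributions are preserved exactly.
    ou_correlation_ps: float | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        k = len(self.states)
        if T.shape != (k, k):
            raise ValueError("transition matrix shape must match the state count")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10) or np.any(T < 0):
            raise ValueError("rows of the jump matrix must be non-negative and sum to 1")
        object.__setattr__(self, "transition_matrix", T)

    @property
    def stationary(self) -> np.ndarray:
        lam, V = np.linalg.eig(self.transition_matrix.T)
        pi = np.abs(np.real(V[:, np.argmin(np.abs(lam - 1.0))]))
        return pi / pi.sum()

    @property
    def relaxation_times(self) -> np.ndarray:
        """Planted relaxation timescales in ps: -dt/ln|lambda_i|, descending."""
        lam = np.sort(np.abs(np.linalg.eigvals(self.transition_matrix)))[::-1][1:]
        with np.errstate(divide="ignore"):
            t = np.where((lam > 0) & (lam < 1), -self.dt / np.log(lam), np.nan)
        return t


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that an estimator must recover."""

    state_path: np.ndarray
    state_names: tuple[str, ...]
    occupancies: np.ndarray
    relaxation_times_ps: np.ndarray
    dominant_pathway: tuple[str, ...] | None
    state_mean_efficiency: np.ndarray | None = None
    mixture_mean_efficiency: float | None = None


def _sample_hidden_chain(T: np.ndarray, n: int, rng: np.random.Generator,
                         pi0: np.ndarray) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    path = np.empty(n, dtype=np.int64)
    path[0] = rng.choice(len(pi0), p=pi0)
    u = rng.random(n)
    for t in range(1, n):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t])
    return path


def _reflect_theta(x: np.ndarray) -> np.ndarray:
    """Fold angles into [0, pi] by reflection."""
    x = np.mod(x, 2 * np.pi)
    x = np.where(x > np.pi, 2 * np.pi - x, x)
    return x


def _wrap_phi(x: np.ndarray) -> np.ndarray:
    return np.mod(x + np.pi, 2 * np.pi) - np.pi


def _sample_state_geometry(state: StateSpec, n: int, rng: np.random.Generator):
    """Draw (R_DA, theta_D, theta_A, phi) n times from one state."""
    r = state.r_median * np.exp(rng.normal(0.0, state.sigma_log, n)) \
        if state.sigma_log > 0 else np.full(n, state.r_median)
    if state.angular_sigma > 0:
        td = _reflect_theta(rng.normal(state.theta_D, state.angular_sigma, n))
        ta = _reflect_theta(rng.normal(state.theta_A, state.angular_sigma, n))
        ph = _wrap_phi(rng.normal(state.phi, state.angular_sigma, n))
    else:
        td = np.full(n, state.theta_D)
        ta = np.full(n, state.theta_A)
        ph = np.full(n, state.phi)
    return r, td, ta, ph


def simulate_scenario(spec: ScenarioSpec, n_frames: int, seed: int = 0,
                      params: ForsterPairParams | None = None
                      ) -> tuple[list[GeometryFrame], GroundTruth]:
    """Simulate a geometry trajectory with a hidden metastable state path.

    Per frame the donor reference point sits at the origin, the acceptor at
    distance R_DA along a random direction, and the two unit dipoles are
    constructed to realize the sampled (theta_D, theta_A, phi) exactly.  With
    ``params`` given, the ground truth also carries Monte-Carlo per-state and
    mixture mean efficiencies (10^5 draws).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(spec.states)
    path = _sample_hidden_chain(spec.transition_matrix, n_frames, rng, spec.stationary)
    # standard-normal deviates behind (R_DA, theta_D, theta_A, phi); an OU
    # recursion correlates them inside each dwell without touching marginals
    z = rng.normal(size=(n_frames, 4))
    if spec.ou_correlation_ps is not None:
        a = np.exp(-spec.dt / spec.ou_correlation_ps)
        b = np.sqrt(1.0 - a * a)
        for t in range(1, n_frames):
            if path[t] == path[t - 1]:
                z[t] = a * z[t - 1] + b * z[t]
    r = np.empty(n_frames)
    td = np.empty(n_frames)
    ta = np.empty(n_frames)
    ph = np.empty(n_frames)
    for s in range(k):
        mask = path == s
        if mask.any():
            st = spec.states[s]
            r[mask] = st.r_median * np.exp(st.sigma_log * z[mask, 0])
            td[mask] = _reflect_theta(st.theta_D + st.angular_sigma * z[mask, 1])
            ta[mask] = _reflect_theta(st.theta_A + st.angular_sigma * z[mask, 2])
            ph[mask] = _wrap_phi(st.phi + st.angular_sigma * z[mask, 3])
    # random separation direction and in-plane frame per frame
    u = rng.normal(size=(n_frames, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    helper = rng.normal(size=(n_frames, 3))
    e1 = helper - (np.einsum("ij,ij->i", helper, u))[:, None] * u
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    alpha = rng.uniform(0.0, 2 * np.pi, n_frames)
    in_d = np.cos(alpha)[:, None] * e1 + np.sin(alpha)[:, None] * e2
    in_a = np.cos(alpha + ph)[:, None] * e1 + np.sin(alpha + ph)[:, None] * e2
    mu_d = np.cos(td)[:, None] * u + np.sin(td)[:, None] * in_d
    mu_a = np.cos(ta)[:, None] * u + np.sin(ta)[:, None] * in_a
    times = np.arange(n_frames) * spec.dt
    zero = np.zeros(3)
    frames = [GeometryFrame(float(times[i]), zero, r[i] * u[i], mu_d[i], mu_a[i])
              for i in range(n_frames)]
    state_means = mixture = None
    if params is not None:
        per_state, mixture, _ = theoretical_mean_efficiency(
            spec, params, n_draws=100_000, seed=seed + 1)
        state_means = per_state
    truth = GroundTruth(
        state_path=path,
        state_names=tuple(s.name for s in spec.states),
        occupancies=spec.stationary,
        relaxation_times_ps=spec.relaxation_times,
        dominant_pathway=spec.dominant_pathway,
        state_mean_efficiency=state_means,
        mixture_mean_efficiency=mixture,
    )
    return frames, truth


def theoretical_mean_efficiency(spec: ScenarioSpec, params: ForsterPairParams,
                                n_draws: int = 1_000_000, seed: int = 0
                                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Monte-Carlo expectation of the transfer efficiency per state.

    Returns (per-state means, occupancy-weighted mixture mean, per-state
    standard errors).  Serves as the independent oracle for trajectory-based
    mean efficiencies.
    """
    rng = np.random.default_rng(seed)
    means = np.empty(len(spec.states))
    ses = np.empty(len(spec.states))
    for i, state in enumerate(spec.states):
        r, td, ta, ph = _sample_state_geometry(state, n_draws, rng)
        k2 = kappa_squared_angles(td, ta, ph)
        k2_eff = k2 if params.kappa2 == "dynamic" else float(params.kappa2)
        r0 = forster_radius(params.J, k2_eff, params.phiD0, params.n)
        e = fret_efficiency(r, np.broadcast_to(np.asarray(r0), r.shape))
        means[i] = e.mean()
        ses[i] = e.std(ddof=1) / np.sqrt(n_draws)
    mixture = float(spec.stationary @ means)
    return means, mixture, ses


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _two_state(p_fold_occupancy: float) -> ScenarioSpec:
    p_escape_folded = 0.004
    # detailed balance: pi_f * p_fu = pi_u * p_uf
    p_uf = p_escape_folded * p_fold_occupancy / (1.0 - p_fold_occupancy)
    folded = StateSpec("folded", r_median=0.9, sigma_log=0.15,
                       theta_D=np.pi / 2, theta_A=np.pi / 2, phi=0.3,
                       angular_sigma=0.35)
    unfolded = StateSpec("unfolded", r_median=2.5, sigma_log=0.12,
                         theta_D=0.9, theta_A=2.0, phi=1.2, angular_sigma=0.5)
    T = np.array([[1 - p_escape_folded, p_escape_folded],
                  [p_uf, 1 - p_uf]])
    return ScenarioSpec(states=(folded, unfolded), transition_matrix=T)


def _six_well() -> ScenarioSpec:
    names = ["A", "S1", "S2", "S3", "S4", "B"]
    r_medians = [2.6, 2.1, 1.7, 1.35, 1.05, 0.8]
    thetas = [0.35, 0.85, 1.35, 1.85, 2.35, 2.80]
    states = tuple(
        StateSpec(nm, r_median=r, sigma_log=0.04, theta_D=th,
                  theta_A=np.pi - th, phi=0.4, angular_sigma=0.08)
        for nm, r, th in zip(names, r_medians, thetas))
    # reversible chain from symmetric edge conductances and target occupancies:
    # T_ij = c_ij / pi_i satisfies detailed balance by construction.  A feeds
    # three parallel branches toward S4; the S3 branch carries most flux.
    pi = np.array([0.20, 0.10, 0.15, 0.20, 0.20, 0.15])
    edges = {(0, 3): 1.5e-3, (0, 2): 4e-4, (0, 1): 2e-4,
             (1, 4): 2e-4, (2, 4): 4e-4, (3, 4): 1.5e-3,
             (4, 5): 1.2e-3}
    T = np.zeros((6, 6))
    for (i, j), c in edges.items():
        T[i, j] = c / pi[i]
        T[j, i] = c / pi[j]
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    return ScenarioSpec(states=states, transition_matrix=T,
                        dominant_pathway=("A", "S3", "S4", "B"))


PRESETS = {
    # hetero-pair-like tether: moderate folded occupancy
    "EZ-like": lambda: _two_state(0.55),
    # homo-pair-like tether: compact conformations dominate
    "EE-like": lambda: _two_state(0.80),
    "two-state-minimal": lambda: _two_state(0.70),
    "six-well": _six_well,
}


def preset_scenario(name: str) -> ScenarioSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]()


def dcm_like_spectra(grid: np.ndarray | None = None) -> tuple[Spectrum, Spectrum]:
    """DCM-like synthetic bands: absorption max 457 nm, emission max 590 nm.

    The absorption peak absorptivity (48 700 M^-1 cm^-1) matches the DCM
    monomer; band widths are plausible for a donor-pi-acceptor dye.
    """
    if grid is None:
        grid = np.arange(300.0, 801.0, 1.0)
    absorption = gaussian_spectrum(457.0, 90.0, 48700.0, grid, "absorption")
    emission = gaussian_spectrum(590.0, 95.0, 1.0, grid, "emission")
    return absorption, emission


def write_fixture_bundle(outdir: str | Path, preset: str, n_frames: int = 2000,
                         seed: int = 0) -> dict[str, Path]:
    """Write a reproducible fixture bundle for one preset scenario.

    Emits the geometry-table trajectory, DCM-like spectra CSVs, the ground
    truth as JSON and a config JSON from which the bundle regenerates
    bitwise-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = preset_scenario(preset)
    frames, truth = simulate_scenario(spec, n_frames, seed=seed)
    files = {
        "trajectory": outdir / "trajectory.dat",
        "absorption": outdir / "acceptor_absorption.csv",
        "emission": outdir / "donor_emission.csv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    write_geometry_table(frames, files["trajectory"])
    absorption, emission = dcm_like_spectra()
    absorption.write_csv(files["absorption"])
    emission.write_csv(files["emission"])
    truth_payload = {
        "state_names": list(truth.state_names),
        "state_path": truth.state_path.tolist(),
        "occupancies": truth.occupancies.tolist(),
        "relaxation_times_ps": [None if np.isnan(t) else t
                                for t in truth.relaxation_times_ps],
        "dominant_pathway": list(truth.dominant_pathway) if truth.dominant_pathway else None,
    }
    files["ground_truth"].write_text(json.dumps(truth_payload, indent=1))
    files["config"].write_text(json.dumps(
        {"preset": preset, "n_frames": n_frames, "seed": seed}, indent=1))
    return files
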