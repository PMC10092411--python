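"""Chromophore-pair geometry trajectories and instantaneous FRET traces.

A trajectory is a sequence of :class:`GeometryFrame` records: per-frame
reference points (nm) and unit transition-dipole vectors for the donor and
acceptor.  From these the module derives the pair geometry (R_DA, angles,
kappa^2), the instantaneous transfer efficiency E(t) with a per-frame
("dynamic") or fixed orientation factor, efficiency histograms, and
distance-stratified statistics.

On-disk dialect (geometry table): whitespace-separated floats, one frame per
line, with the header::

    # time_ps refDx refDy refDz refAx refAy refAz muDx muDy muDz muAx muAy muAz

Units are nm and ps, declared by the header; gzip-compressed files are
accepted transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .forster import (ForsterPairParams, PairGeometry, forster_radius,
                      fret_efficiency, kappa_squared_vectors)

GEOMETRY_HEADER = ("# time_ps refDx refDy refDz refAx refAy refAz "
                   "muDx muDy muDz muAx muAy muAz")


@dataclass(frozen=True)
class GeometryFrame:
    """One trajectory frame: time (ps), reference points (nm), unit dipoles."""

    time: float
    ref_D: np.ndarray
    ref_A: np.ndarray
    mu_D: np.ndarray
    mu_A: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ref_D", "ref_A", "mu_D", "mu_A"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        for name in ("mu_D", "mu_A"):
            v = getattr(self, name)
            norm = np.linalg.norm(v)
            if abs(norm - 1.0) > 0.1:
                raise ValueError(f"{name} deviates from unit length by more than 10%")
            if abs(norm - 1.0) > 1e-9:   # keep already-unit vectors bitwise intact
                object.__setattr__(self, name, v / norm)


@dataclass(frozen=True)
class ChromophoreDef:
    """Atom selection defining one chromophore in an atomistic frame.

    ``atoms`` are indices into the coordinate array, ``masses`` their masses,
    and ``dipole_axis`` an ordered pair of atom indices (members of ``atoms``)
    whose difference vector gives the transition-dipole direction.
    """

    atoms: tuple[int, ...]
    masses: tuple[float, ...]
    dipole_axis: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.atoms) < 2:
            raise ValueError("a chromophore needs at least two atoms")
        if len(self.masses) != len(self.atoms):
            raise ValueError("one mass per atom required")
        if any(a not in self.atoms for a in self.dipole_axis):
            raise ValueError("dipole axis atoms must belong to the chromophore")


@dataclass(frozen=True)
class FretTrace:
    """Instantaneous FRET observables along a trajectory.

    All arrays share the same length; ``efficiency`` is recomputable from
    (R_DA, kappa2) and the stored parameters.
    """

    times: np.ndarray        # ps
    R_DA: np.ndarray         # nm
    kappa2: np.ndarray
    efficiency: np.ndarray
    params: ForsterPairParams

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("times", "R_DA", "kappa2", "efficiency"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError("trace arrays must share one length")
            object.__setattr__(self, name, v)
        if n and (self.efficiency.min() < -1e-12 or self.efficiency.max() > 1 + 1e-12):
            raise ValueError("efficiencies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def mean_efficiency(self) -> float:
        return float(self.efficiency.mean())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def load_geometry_table(path: str | Path) -> list[GeometryFrame]:
    """Read a geometry-table trajectory; frames must be in time order."""
    frames: list[GeometryFrame] = []
    last_t = -np.inf
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 13:
                raise ValueError(f"{path}:{lineno}: expected 13 columns, got {len(parts)}")
            try:
                vals = np.array([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed float") from exc
            if vals[0] < last_t:
                raise ValueError(f"{path}:{lineno}: time not non-decreasing")
            last_t = vals[0]
            frames.append(GeometryFrame(vals[0], vals[1:4], vals[4:7],
                                        vals[7:10], vals[10:13]))
    return frames


def write_geometry_table(frames: Sequence[GeometryFrame], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(GEOMETRY_HEADER + "\n")
        for f in frames:
            row = np.concatenate([[f.time], f.ref_D, f.ref_A, f.mu_D, f.mu_A])
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


def frames_from_atomistic(coordinates: np.ndarray, times: np.ndarray,
                          chrom_D: ChromophoreDef, chrom_A: ChromophoreDef,
                          length_scale: float = 1.0) -> list[GeometryFrame]:
    """Build geometry frames from raw atomistic coordinates.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in nm (multiply by
    ``length_scale`` to convert, e.g. 0.1 for angstrom input).  The reference
    point of each chromophore is the position of the atom nearest its mass
    center; the dipole direction is the normalized difference of the two
    ``dipole_axis`` atoms.
    """
    coordinates = np.asarray(coordinates, dtype=float) * length_scale
    frames = []
    for t, xyz in zip(times, coordinates):
        refs, mus = [], []
        for cd in (chrom_D, chrom_A):
            pos = xyz[list(cd.atoms)]
            m = np.asarray(cd.masses)
            com = (pos * m[:, None]).sum(axis=0) / m.sum()
            nearest = int(np.argmin(np.linalg.norm(pos - com, axis=1)))
            refs.append(pos[nearest])
            axis = xyz[cd.dipole_axis[1]] - xyz[cd.dipole_axis[0]]
            mus.append(axis / np.linalg.norm(axis))
        frames.append(GeometryFrame(float(t), refs[0], refs[1], mus[0], mus[1]))
    return frames


def frames_from_mdanalysis(universe, sel_D: str, sel_A: str,
                           axis_D: tuple[str, str], axis_A: tuple[str, str]):
    """Adapter from an MDAnalysis Universe (GRO/XTC and friends).

    ``sel_D``/``sel_A`` are MDAnalysis selection strings for the two
    chromophores; ``axis_D``/``axis_A`` name the two atoms (selection strings)
    spanning each transition-dipole axis.  MDAnalysis works in angstrom; the
    output is in nm and ps.
    """
    groups = (universe.select_atoms(sel_D), universe.select_atoms(sel_A))
    axes = (tuple(universe.select_atoms(s) for s in axis_D),
            tuple(universe.select_atoms(s) for s in axis_A))
    frames = []
    for ts in universe.trajectory:
        refs, mus = [], []
        for g, ax in zip(groups, axes):
            com = g.center_of_mass()
            nearest = int(np.argmin(np.linalg.norm(g.positions - com, axis=1)))
            refs.append(g.positions[nearest] * 0.1)
            v = (ax[1].positions[0] - ax[0].positions[0])
            mus.append(v / np.linalg.norm(v))
        frames.append(GeometryFrame(float(ts.time), refs[0], refs[1], mus[0], mus[1]))
    return frames


# ---------------------------------------------------------------------------
# Geometry and traces
# ---------------------------------------------------------------------------

def geometry_features(frames: Sequence[GeometryFrame]) -> np.ndarray:
    """Per-frame feature matrix (R_DA, theta_D, theta_A) for MSM featurization.

    These geometric observables are what the downstream tICA/MSM pipeline
    consumes; angles are in radians, distances in nm.
    """
    rv = np.array([f.ref_A - f.ref_D for f in frames])
    rn = np.linalg.norm(rv, axis=1)
    if np.any(rn <= 0):
        raise ValueError("coincident reference points")
    rh = rv / rn[:, None]
    mu_d = np.array([f.mu_D for f in frames])
    mu_a = np.array([f.mu_A for f in frames])
    td = np.arccos(np.clip(np.einsum("ij,ij->i", mu_d, rh), -1.0, 1.0))
    ta = np.arccos(np.clip(np.einsum("ij,ij->i", mu_a, rh), -1.0, 1.0))
    return np.column_stack([rn, td, ta])


def pair_geometry(frame: GeometryFrame) -> PairGeometry:
    """Pair geometry (R_DA, theta_D, theta_A, phi) of a single frame."""
    R_vec = frame.ref_A - frame.ref_D
    if np.linalg.norm(R_vec) <= 0:
        raise ValueError("coincident chromophore reference points")
    _, geom = kappa_squared_vectors(frame.mu_D, frame.mu_A, R_vec)
    return geom


def fret_trace(frames: Sequence[GeometryFrame], params: ForsterPairParams) -> FretTrace:
    """Instantaneous E(t) along a trajectory.

    With the default ``kappa2="dynamic"`` policy the per-frame orientation
    factor enters the Forster radius, so R0 varies frame by frame; a numeric
    ``params.kappa2`` freezes the orientation factor instead.
    """
    if not frames:
        raise ValueError("empty trajectory")
    times = np.array([f.time for f in frames])
    r_vecs = np.array([f.ref_A - f.ref_D for f in frames])
    mu_d = np.array([f.mu_D for f in frames])
    mu_a = np.array([f.mu_A for f in frames])
    r_da = np.linalg.norm(r_vecs, axis=1)
    if np.any(r_da <= 0):
        raise ValueError("coincident reference points in trajectory")
    r_hat = r_vecs / r_da[:, None]
    kappa = (np.einsum("ij,ij->i", mu_d, mu_a)
             - 3.0 * np.einsum("ij,ij->i", mu_d, r_hat)
             * np.einsum("ij,ij->i", mu_a, r_hat))
    kappa2 = kappa**2
    k2_eff = kappa2 if params.kappa2 == "dynamic" else np.full_like(kappa2, float(params.kappa2))
    r0 = forster_radius(params.J, k2_eff, params.phiD0, params.n)
    eff = fret_efficiency(r_da, r0)
    return FretTrace(times, r_da, kappa2, np.atleast_1d(eff), params)


def efficiency_histogram(trace: FretTrace, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of E over [0, 1]; counts sum to the number of frames."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(trace.efficiency, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


@dataclass(frozen=True)
class DistanceStratification:
    """Frame counts and mean efficiencies per interchromophoric-distance class.

    With the default edges (1, 2) nm the classes are R_DA <= 1,
    1 < R_DA < 2 and R_DA >= 2 (closed outer bounds); empty classes report a
    NaN mean rather than zero.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]
    counts: np.ndarray
    mean_efficiency: np.ndarray
    overall_mean: float

    def as_dict(self) -> dict:
        return {
            "edges_nm": list(self.edges),
            "classes": [
                {"label": lab, "n_frames": int(c),
                 "mean_efficiency": None if np.isnan(m) else float(m)}
                for lab, c, m in zip(self.labels, self.counts, self.mean_efficiency)
            ],
            "overall_mean_efficiency": self.overall_mean,
        }


def stratify_by_distance(trace: FretTrace,
                         edges: Sequence[float] = (1.0, 2.0)) -> DistanceStratification:
    """Mean E per distance class, boundary frames in the closed-bound classes."""
    edges = tuple(float(e) for e in edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    r = trace.R_DA
    # class 0: r <= e0; middle classes: e_{i-1} < r < e_i; last: r >= e_last
    idx = np.searchsorted(np.asarray(edges), r, side="right")
    idx[r == edges[0]] = 0                    # R_DA <= e0 is closed
    idx[r >= edges[-1]] = len(edges)          # R_DA >= e_last is closed
    n_classes = len(edges) + 1
    counts = np.bincount(idx, minlength=n_classes)
    means = np.full(n_classes, np.nan)
    for k in range(n_classes):
        mask = idx == k
        if mask.any():
            means[k] = trace.efficiency[mask].mean()
    labels = [f"R_DA <= {edges[0]:g}"]
    labels += [f"{a:g} < R_DA < {b:g}" for a, b in zip(edges, edges[1:])]
    labels += [f"R_DA >= {edges[-1]:g}"]
    overall = trace.mean_efficiency if len(trace) else float("nan")
    return DistanceStratification(edges, tuple(labels), counts, means, overall)


def window_extract(trace: FretTrace, t_start: float, t_end: float) -> FretTrace:
    """Sub-trace with times in [t_start, t_end]; empty windows are allowed."""
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    mask = (trace.times >= t_start) & (trace.times <= t_end)
    return FretTrace(trace.times[mask], trace.R_DA[mask], trace.kappa2[mask],
                     trace.efficiency[mask], trace.params)
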