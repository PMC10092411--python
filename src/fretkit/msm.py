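"""Markov-state-model decomposition of conformational trajectories.

Pipeline: featurized frames -> tICA projection onto slow coordinates ->
k-means microstates -> transition-matrix estimation at a lag time (validated
by implied timescales and the Chapman-Kolmogorov test) -> PCCA+ lumping into
metastable sets -> transition-path-theory fluxes and pathway percentages ->
free-energy landscapes over the leading independent components.

Conventions: lags are in frames; free energies are in units of k_B*T with the
global minimum shifted to zero; all estimators are deterministic given the
input (k-means takes an explicit seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

__all__ = [
    "TICAModel", "tica_fit", "cluster_kmeans", "MarkovModel", "estimate_msm",
    "implied_timescales", "ck_test", "MetastablePartition", "pcca",
    "FluxNetwork", "coarse_fluxes", "FEL", "free_energy_surface",
    "pca_cosine_content",
]


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TICAModel:
    """Solution of the symmetrized time-lagged generalized eigenproblem.

    Eigenvalues are the lag-time autocorrelations of the independent
    components, sorted descending; implied timescales are -lag/ln|lambda|.
    """

    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray   # columns, C0-orthonormal

    def transform(self, X: np.ndarray, n_components: int | None = None,
                  scale: str = "whitened") -> np.ndarray:
        """Project onto the independent components.

        ``scale="whitened"`` gives unit instantaneous variance per component;
        ``scale="kinetic"`` additionally weights each component by its
        (non-negative part of the) eigenvalue, so Euclidean distances in the
        projected space approximate kinetic distances — the right metric for
        microstate clustering, since it suppresses fast noise directions.
        """
        X = np.asarray(X, dtype=float)
        Y = (X - self.mean) @ self.eigenvectors
        if scale == "kinetic":
            Y = Y * np.clip(self.eigenvalues, 0.0, None)[None, :]
        elif scale != "whitened":
            raise ValueError("scale must be 'whitened' or 'kinetic'")
        return Y if n_components is None else Y[:, :n_components]

    @property
    def timescales(self) -> np.ndarray:
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            return np.where((lam > 0) & (lam < 1), -self.lag / np.log(lam), np.nan)


def tica_fit(features: np.ndarray, lag: int, epsilon: float = 1e-10) -> TICAModel:
    """Time-lagged independent component analysis of a feature time series.

    Solves C(tau) v = lambda C(0) v with symmetrized covariances estimated
    from mean-free data, C(0) regularized by ``epsilon`` on the diagonal.
    Null directions of C(0) are dropped with a warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.ndim != 2:
        raise ValueError("features must be a (n_frames, n_features) array")
    if X.shape[0] <= lag or lag < 1:
        raise ValueError("need series length > lag >= 1")
    mean = X.mean(axis=0)
    Xc = X - mean
    X0, Xt = Xc[:-lag], Xc[lag:]
    norm = X0.shape[0]
    C0 = 0.5 * (X0.T @ X0 + Xt.T @ Xt) / norm
    Ct = 0.5 * (X0.T @ Xt + Xt.T @ X0) / norm
    # drop numerically null directions of C0 before whitening
    s, U = np.linalg.eigh(C0)
    tol = max(epsilon, 1e-12 * s.max()) if s.size else epsilon
    keep = s > tol
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} null feature direction(s)", stacklevel=2)
    U = U[:, keep]
    s = s[keep]
    C0r = U.T @ C0 @ U + epsilon * np.eye(keep.sum())
    Ctr = U.T @ Ct @ U
    lam, V = scipy.linalg.eigh(Ctr, C0r)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    return TICAModel(lag=int(lag), mean=mean, eigenvalues=lam, eigenvectors=U @ V)


# ---------------------------------------------------------------------------
# microstate clustering
# ---------------------------------------------------------------------------

def cluster_kmeans(projected: np.ndarray, k: int, seed: int = 0,
                   max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """k-means microstates (Lloyd iterations, k-means++ init, fixed seed).

    Returns (discrete trajectory of microstate indices, cluster centers).
    """
    X = np.atleast_2d(np.asarray(projected, dtype=float))
    if X.shape[0] == X.size:
        X = X.reshape(-1, 1)
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    labels = km.fit_predict(X)
    return labels.astype(np.int64), km.cluster_centers_


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovModel:
    """Row-stochastic transition matrix on the largest connected microstate set.

    ``active_set`` maps the model's state indices back to the original
    microstate labels; ``pi`` is the stationary distribution.
    """

    lag: int
    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    active_set: np.ndarray
    reversible: bool = False

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        lam = np.linalg.eigvals(self.T)
        lam = lam[np.argsort(-np.abs(lam))]
        return lam if k is None else lam[:k]

    def timescales(self, k: int | None = None) -> np.ndarray:
        lam = self.eigenvalues(k=None)[1:]  # skip the stationary eigenvalue
        if k is not None:
            lam = lam[:k]
        out = np.full(lam.shape, np.nan)
        lam_r = np.real(lam)
        good = (lam_r > 0) & (np.abs(lam) < 1)
        out[good] = -self.lag / np.log(np.abs(lam[good]))
        return out


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(lam - 1.0)))
    pi = np.real(V[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 10000) -> np.ndarray:
    """Maximum-likelihood reversible transition matrix (fixed-point iteration)."""
    C = np.asarray(C, dtype=float)
    c_row = C.sum(axis=1)
    X = 0.5 * (C + C.T)
    X /= X.sum()
    for _ in range(max_iter):
        x_row = X.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
            X_new = np.where(C + C.T > 0, (C + C.T) / denom, 0.0)
        X_new /= X_new.sum()
        if np.max(np.abs(X_new - X)) < tol:
            X = X_new
            break
        X = X_new
    x_row = X.sum(axis=1)
    return X / x_row[:, None]


def count_matrix(dtraj: np.ndarray, lag: int, n_states: int | None = None,
                 mode: str = "sliding") -> np.ndarray:
    """Transition counts at the given lag (sliding-window by default)."""
    dtraj = np.asarray(dtraj, dtype=np.int64)
    if lag < 1 or len(dtraj) <= lag:
        raise ValueError("need lag >= 1 and trajectory longer than lag")
    if n_states is None:
        n_states = int(dtraj.max()) + 1
    step = 1 if mode == "sliding" else lag
    i, j = dtraj[:-lag:step], dtraj[lag::step]
    C = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(C, (i, j), 1)
    return C


def estimate_msm(dtraj: np.ndarray, lag: int, reversible: bool = False,
                 count_mode: str = "sliding") -> MarkovModel:
    """Estimate a Markov state model from a discrete trajectory.

    Counts are restricted to the largest strongly connected set; the
    non-reversible estimator row-normalizes the counts, the reversible one
    runs the detailed-balance maximum-likelihood fixed point.
    """
    C = count_matrix(dtraj, lag, mode=count_mode)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        C > 0, directed=True, connection="strong")
    sizes = np.array([C[labels == c].sum() for c in range(n_comp)])
    largest = int(np.argmax(sizes))
    active = np.where(labels == largest)[0]
    if len(active) < C.shape[0]:
        retained = C[np.ix_(active, active)].sum() / max(C.sum(), 1)
        warnings.warn(
            f"disconnected trajectory: retaining {len(active)}/{C.shape[0]} states "
            f"({100 * retained:.1f}% of counts)", stacklevel=2)
    Ca = C[np.ix_(active, active)].astype(float)
    if reversible:
        T = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
    pi = _stationary_distribution(T)
    return MarkovModel(lag=int(lag), counts=Ca.astype(np.int64), T=T, pi=pi,
                       active_set=active, reversible=reversible)


def implied_timescales(dtraj: np.ndarray, lags, n_timescales: int = 5,
                       reversible: bool = False) -> dict[int, np.ndarray]:
    """Implied timescales t_i(tau) = -tau/ln|lambda_i(tau)| per candidate lag.

    Eigenvalues with non-positive real part yield NaN (undefined timescale).
    """
    out: dict[int, np.ndarray] = {}
    for lag in lags:
        model = estimate_msm(dtraj, lag, reversible=reversible)
        out[int(lag)] = model.timescales(k=n_timescales)
    return out


def ck_test(dtraj: np.ndarray, lag: int, multiples, n_macro: int,
            reversible: bool = False) -> dict:
    """Chapman-Kolmogorov test on metastable-set self-transition probabilities.

    Compares [T(lag)]^k against the directly re-estimated T(k*lag), both
    aggregated over the PCCA+ metastable sets of the lag-time model.  Returns
    predicted/estimated curves per set and the maximum absolute deviation.
    """
    model = estimate_msm(dtraj, lag, reversible=reversible)
    part = pcca(model, n_macro)
    sets = [np.where(part.assignments == m)[0] for m in range(n_macro)]

    def set_self_probs(T: np.ndarray, pi: np.ndarray) -> np.ndarray:
        probs = np.empty(n_macro)
        for m, s in enumerate(sets):
            w = pi[s]
            probs[m] = (w[:, None] * T[np.ix_(s, s)]).sum() / w.sum()
        return probs

    multiples = [int(k) for k in multiples]
    predicted = np.empty((len(multiples), n_macro))
    estimated = np.empty((len(multiples), n_macro))
    for row, k in enumerate(multiples):
        predicted[row] = set_self_probs(np.linalg.matrix_power(model.T, k), model.pi)
        mk = estimate_msm(dtraj, k * lag, reversible=reversible)
        if not np.array_equal(mk.active_set, model.active_set):
            warnings.warn(f"active set changed at lag {k * lag}; comparison on overlap",
                          stacklevel=2)
        common = np.intersect1d(mk.active_set, model.active_set)
        remap = {s: i for i, s in enumerate(mk.active_set)}
        idx = np.array([remap[s] for s in common])
        Tk = mk.T[np.ix_(idx, idx)]
        Tk = Tk / Tk.sum(axis=1, keepdims=True)
        estimated[row] = set_self_probs(Tk, mk.pi[idx] / mk.pi[idx].sum())
    return {
        "multiples": multiples,
        "predicted": predicted,
        "estimated": estimated,
        "max_deviation": float(np.max(np.abs(predicted - estimated))),
    }


# ---------------------------------------------------------------------------
# PCCA+
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetastablePartition:
    """Fuzzy PCCA+ memberships (rows on the simplex) and crisp assignments."""

    memberships: np.ndarray      # (n_states, m)
    assignments: np.ndarray      # argmax per state

    @property
    def n_metastable(self) -> int:
        return self.memberships.shape[1]


def pcca(model: MarkovModel, m: int) -> MetastablePartition:
    """PCCA+ metastable lumping (Roeblitz-Weber inner-simplex algorithm).

    Uses the top-m right eigenvectors of T, locates the m most spread-out
    states as simplex vertices, and maps the eigenvector rows onto membership
    coordinates, clipped to the simplex and row-renormalized.
    """
    if m < 1 or m > model.n_states:
        raise ValueError("need 1 <= m <= n_states")
    if m == 1:
        memb = np.ones((model.n_states, 1))
        return MetastablePartition(memb, np.zeros(model.n_states, dtype=int))
    lam, V = np.linalg.eig(model.T)
    order = np.argsort(-np.real(lam))
    lam, V = lam[order[:m]], V[:, order[:m]]
    if np.max(np.abs(np.imag(lam))) > 1e-8:
        warnings.warn("complex eigenvalues in the top-m block; using real parts",
                      stacklevel=2)
    V = np.real(V)
    # normalize sign/scale: first eigenvector is constant -> set to 1
    V = V / V[:, 0][:, None] if np.all(np.abs(V[:, 0]) > 1e-12) else V
    V[:, 0] = 1.0
    # inner simplex algorithm: find m vertex states
    ortho = V.copy()
    ind = np.zeros(m, dtype=int)
    ind[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho -= ortho[ind[0]]
    for j in range(1, m):
        dist = np.linalg.norm(ortho, axis=1)
        ind[j] = int(np.argmax(dist))
        v = ortho[ind[j]]
        nv = np.linalg.norm(v)
        if nv > 0:
            v = v / nv
            ortho -= np.outer(ortho @ v, v)
    W = np.linalg.inv(V[ind])
    chi = V @ W
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    chi = chi / rows
    assign = np.argmax(chi, axis=1)
    # every metastable set must be non-empty under crisp assignment
    for j in range(m):
        if not np.any(assign == j):
            assign[ind[j]] = j
    return MetastablePartition(chi, assign)


# ---------------------------------------------------------------------------
# transition path theory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxNetwork:
    """TPT reactive flux between a source and a sink metastable set.

    ``net_flux`` is the coarse-grained net flux matrix (per lag time unit),
    ``pathways`` the bottleneck decomposition as (path, flux, fraction)
    with fractions relative to the total reactive flux.
    """

    total_flux: float
    net_flux: np.ndarray
    committor_forward: np.ndarray   # per microstate
    committor_backward: np.ndarray
    micro_net_flux: np.ndarray
    pathways: tuple

    def pathway_percentages(self) -> list[tuple[tuple[int, ...], float]]:
        return [(p, 100.0 * frac) for p, _, frac in self.pathways]


def _committor(T: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Forward committor: probability of hitting B before A."""
    n = T.shape[0]
    q = np.zeros(n)
    q[B] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if interior.size:
        M = np.eye(interior.size) - T[np.ix_(interior, interior)]
        b = T[np.ix_(interior, B)].sum(axis=1)
        q[interior] = np.linalg.solve(M, b)
    return q


def _widest_path(F: np.ndarray, sources: np.ndarray, sinks: np.ndarray):
    """Max-bottleneck path in a flux network (Dijkstra on min-edge capacity)."""
    n = F.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1)
    width[sources] = np.inf
    visited = np.zeros(n, dtype=bool)
    while True:
        cand = np.where(~visited, width, -np.inf)
        u = int(np.argmax(cand))
        if cand[u] <= 0:
            return None, 0.0
        if u in sinks:
            path = [u]
            while prev[path[-1]] >= 0:
                path.append(int(prev[path[-1]]))
            if path[-1] not in sources:
                return None, 0.0
            return tuple(reversed(path)), float(width[u])
        visited[u] = True
        for v in range(n):
            if F[u, v] > 0:
                w = min(width[u], F[u, v])
                if w > width[v]:
                    width[v] = w
                    prev[v] = u


def coarse_fluxes(model: MarkovModel, partition: MetastablePartition | None,
                  source_set, sink_set, max_pathways: int = 50,
                  flux_fraction: float = 0.999) -> FluxNetwork:
    """TPT reactive flux, coarse-grained over metastable sets, with pathways.

    ``source_set``/``sink_set`` are metastable-set indices (``partition=None``
    treats each microstate as its own set).  The committors are solved on the
    microstate chain; the gross reactive flux f_ij = pi_i q-_i T_ij q+_j is
    netted, summed over set pairs, and decomposed into pathways by iterative
    removal of max-bottleneck paths; the percentage of a pathway is its flux
    over the total reactive flux.
    """
    source_set = np.atleast_1d(np.asarray(source_set, dtype=int))
    sink_set = np.atleast_1d(np.asarray(sink_set, dtype=int))
    if np.intersect1d(source_set, sink_set).size:
        raise ValueError("source and sink sets must be disjoint")
    n = model.n_states
    if partition is None:
        assign = np.arange(n)
        n_sets = n
    else:
        assign = partition.assignments
        n_sets = partition.n_metastable
    A = np.where(np.isin(assign, source_set))[0]
    B = np.where(np.isin(assign, sink_set))[0]
    if A.size == 0 or B.size == 0:
        raise ValueError("empty source or sink set")
    T, pi = model.T, model.pi
    qp = _committor(T, A, B)
    # backward committor via the time-reversed chain
    with np.errstate(divide="ignore", invalid="ignore"):
        T_rev = (pi[None, :] * T.T) / pi[:, None]
    qm = _committor(T_rev, B, A)  # probability of having come from A
    # gross and net reactive flux on microstates
    f = pi[:, None] * qm[:, None] * T * qp[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.clip(f - f.T, 0.0, None)
    total = float(f[A, :][:, np.setdiff1d(np.arange(n), A)].sum())
    # coarse-grain gross flux over metastable sets, then net
    M = np.zeros((n, n_sets))
    M[np.arange(n), assign] = 1.0
    F_gross = M.T @ f @ M
    np.fill_diagonal(F_gross, 0.0)
    F_net = np.clip(F_gross - F_gross.T, 0.0, None)
    # pathway decomposition by iterative bottleneck removal
    paths = []
    if total > 0:
        Fwork = F_net.copy()
        captured = 0.0
        for _ in range(max_pathways):
            path, bottleneck = _widest_path(Fwork, source_set, sink_set)
            if path is None or bottleneck <= 0:
                break
            for u, v in zip(path[:-1], path[1:]):
                Fwork[u, v] -= bottleneck
            paths.append((path, bottleneck, bottleneck / total))
            captured += bottleneck
            if captured >= flux_fraction * total:
                break
    return FluxNetwork(total_flux=total, net_flux=F_net,
                       committor_forward=qp, committor_backward=qm,
                       micro_net_flux=net, pathways=tuple(paths))


# ---------------------------------------------------------------------------
# free-energy landscape and sampling diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FEL:
    """Free-energy landscape F = -ln P on a 2-D grid, in k_B*T units.

    Empty bins carry +inf (no fabricated barriers); the global minimum is
    shifted to zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    counts: np.ndarray

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            P = np.exp(-self.F)
        P[~np.isfinite(self.F)] = 0.0
        return P / P.sum()


def free_energy_surface(projected: np.ndarray, grid_shape=(50, 50),
                        temperature: float = 1.0) -> FEL:
    """Boltzmann inversion of the empirical density over two coordinates.

    F(x, y) = -k_B T ln P(x, y), reported in units of k_B*T (``temperature``
    rescales only if a physical energy unit is wanted; default 1 leaves the
    landscape in k_B*T).
    """
    X = np.atleast_2d(np.asarray(projected, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need two projected coordinates")
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=grid_shape)
    with np.errstate(divide="ignore"):
        F = -np.log(H / H.sum()) * temperature
    F = F - np.nanmin(F[np.isfinite(F)])
    return FEL(xe, ye, F, H.astype(np.int64))


def pca_cosine_content(coordinates: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Cosine content of the leading principal components.

    For the i-th PC projection p_i(t) over T frames,

        c_i = (2/T) * (sum_t cos(i*pi*t/T) p_i(t))^2 / sum_t p_i(t)^2

    c_i near 1 means the PC is indistinguishable from random diffusion
    (poor sampling); well-sampled metastable dynamics gives low values.
    """
    X = np.atleast_2d(np.asarray(coordinates, dtype=float))
    T = X.shape[0]
    if T < 4:
        raise ValueError("need at least 4 frames")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, Vt.shape[0])
    proj = Xc @ Vt[:n_components].T
    t = np.arange(T)
    out = np.empty(n_components)
    for i in range(n_components):
        cos = np.cos((i + 1) * np.pi * t / T)
        p = proj[:, i]
        denom = float(p @ p)
        out[i] = 0.0 if denom == 0 else (2.0 / T) * float(cos @ p) ** 2 / denom
    return out
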