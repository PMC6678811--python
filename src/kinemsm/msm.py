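"""Markov-state-model construction.

The estimation chain mirrors standard MSM practice for conformational
dynamics: a time-lagged independent component analysis (tICA) of the
dihedral feature matrix extracts the slowest linear collective coordinates;
k-means partitions the embedded conformations into microstates; transitions
are counted at a lag time within each contiguous run; a maximum-likelihood
(optionally reversible) transition matrix is estimated on the largest
strongly connected set; and PCCA+ lumps the microstates into metastable
macrostates.  Model validity is judged by lag-independence of the implied
timescales tₖ(τ) = −τ/ln λₖ(τ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse.csgraph

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteTrajectory",
    "TICAModel",
    "CountMatrix",
    "MarkovModel",
    "MacroAssignment",
    "MicrostateModel",
    "fit_tica",
    "transform_tica",
    "cluster_kmeans",
    "count_transitions",
    "estimate_markov_model",
    "implied_timescales",
    "select_lag",
    "pcca_plus",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DiscreteTrajectory:
    """Microstate index sequences, one array per contiguous run."""

    segments: list[np.ndarray]
    frame_interval_ns: float = 1.0

    def __post_init__(self):
        self.segments = [np.asarray(s, dtype=np.int64).reshape(-1)
                         for s in self.segments]
        if not self.segments or any(s.size == 0 for s in self.segments):
            raise ValueError("empty discrete trajectory")
        if any(s.min() < 0 for s in self.segments):
            raise ValueError("negative state index")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")

    @property
    def n_states(self) -> int:
        return int(max(s.max() for s in self.segments)) + 1

    @property
    def n_frames(self) -> int:
        return int(sum(s.size for s in self.segments))

    @classmethod
    def from_array(cls, states, frame_interval_ns: float = 1.0,
                   boundaries: tuple[int, ...] = ()):
        states = np.asarray(states, dtype=np.int64).reshape(-1)
        edges = [0, *sorted(boundaries), states.size]
        segs = [states[a:b] for a, b in zip(edges[:-1], edges[1:])]
        return cls(segs, frame_interval_ns)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.segments)


@dataclass
class TICAModel:
    """Result of the symmetrized generalized eigenproblem C̃(τ)v = λC(0)v."""

    mean: np.ndarray
    c0: np.ndarray
    ct: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # (n_features, n_components), C0-orthonormal columns
    lag_frames: int
    dim: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components[:, : self.dim]


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag_frames: int
    lag_ns: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative transition counts")


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix with stationary law and spectrum.

    ``active_set`` maps the model's state indices back to the original
    microstate numbering (largest strongly connected component).
    """

    T: np.ndarray
    pi: np.ndarray
    lag_ns: float
    lag_frames: int
    active_set: np.ndarray
    reversible: bool = True
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.T.shape[0]
        if self.T.shape != (n, n):
            raise ValueError("T must be square")
        if np.any(np.abs(self.T.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("rows of T must sum to 1")
        if abs(self.pi.sum() - 1.0) > 1e-8 or np.any(self.pi <= 0):
            raise ValueError("pi must be a positive distribution")
        if np.max(np.abs(self.pi @ self.T - self.pi)) > 1e-8:
            raise ValueError("pi is not stationary for T")
        self.active_set = np.asarray(self.active_set, dtype=int)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        vals = np.linalg.eigvals(self.T)
        order = np.argsort(-np.abs(vals))
        vals = vals[order]
        return vals if k is None else vals[:k]

    def timescales(self, k: int = 5) -> np.ndarray:
        """Implied timescales (ns) of the k slowest non-stationary modes."""
        vals = self.eigenvalues(k + 1)[1:]
        out = np.full(vals.size, np.nan)
        for i, lam in enumerate(vals):
            mod = float(np.abs(lam))
            if np.isreal(lam) and lam.real <= 0:
                continue
            if 0 < mod < 1:
                out[i] = -self.lag_ns / np.log(mod)
            elif mod >= 1:
                out[i] = np.inf
        return out

    def is_reversible(self, tol: float = 1e-8) -> bool:
        flux = self.pi[:, None] * self.T
        return bool(np.max(np.abs(flux - flux.T)) <= tol)


@dataclass
class MacroAssignment:
    """PCCA+ memberships and crisp microstate→macrostate map."""

    chi: np.ndarray              # (n_micro, n_macro), rows sum to 1
    crisp: np.ndarray            # (n_micro,) argmax macrostate
    populations: np.ndarray      # (n_macro,) sum of pi over crisp members

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=float)
        self.crisp = np.asarray(self.crisp, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        if np.any(self.chi < -1e-10) or np.any(self.chi > 1 + 1e-10):
            raise ValueError("memberships must lie in [0, 1]")
        if np.max(np.abs(self.chi.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("membership rows must sum to 1")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("macrostate populations must sum to 1")
        n_macro = self.chi.shape[1]
        present = np.unique(self.crisp)
        if present.size != n_macro:
            raise ValueError("empty macrostate under the crisp map")

    @property
    def n_macrostates(self) -> int:
        return self.chi.shape[1]

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.crisp == macro)


@dataclass
class MicrostateModel:
    centers: np.ndarray
    inertia: float
    seed: int


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

def fit_tica(features: FeatureMatrix, lag: int, dim: int = 4) -> TICAModel:
    """Time-lagged independent component analysis of a feature matrix.

    Solves C̃(τ)v = λC(0)v with C̃ the symmetrized lagged covariance
    (C(τ)+C(τ)ᵀ)/2, estimated from all frame pairs (t, t+lag) that do not
    straddle a source-file boundary.  Components are C(0)-orthonormal and
    sorted by descending eigenvalue.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    segs = [features.values[a:b] for a, b in features.segments()]
    usable = [s for s in segs if s.shape[0] > lag]
    if not usable:
        raise ValueError(f"no segment longer than lag {lag}")
    nf = features.values.shape[1]
    if dim > nf:
        raise ValueError(f"dim {dim} exceeds feature count {nf}")

    X0 = np.concatenate([s[:-lag] for s in usable])
    Xt = np.concatenate([s[lag:] for s in usable])
    mean = 0.5 * (X0.mean(axis=0) + Xt.mean(axis=0))
    A = X0 - mean
    B = Xt - mean
    N = A.shape[0]
    c0 = 0.5 * (A.T @ A + B.T @ B) / N
    ct = 0.5 * (A.T @ B + B.T @ A) / N

    # regularize a rank-deficient instantaneous covariance
    eigmin = float(np.linalg.eigvalsh(c0).min())
    if eigmin < 1e-12 * max(1.0, float(np.trace(c0))):
        logger.warning("rank-deficient C(0) (min eigenvalue %.3g); "
                       "adding 1e-10 to the diagonal", eigmin)
        c0 = c0 + 1e-10 * np.eye(nf)

    vals, vecs = scipy.linalg.eigh(ct, c0)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, -1.0, 1.0)
    return TICAModel(mean=mean, c0=c0, ct=ct, eigenvalues=vals,
                     components=vecs, lag_frames=lag, dim=dim)


def transform_tica(model: TICAModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = features.values if isinstance(features, FeatureMatrix) else features
    return model.transform(X)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_kmeans(
    projected: np.ndarray | FeatureMatrix,
    k: int,
    seed: int = 0,
    frame_interval_ns: float | None = None,
    boundaries: tuple[int, ...] = (),
) -> tuple[MicrostateModel, DiscreteTrajectory]:
    """k-means microstates (Lloyd's algorithm, k-means++ init, fixed seed)."""
    from sklearn.cluster import KMeans

    if isinstance(projected, FeatureMatrix):
        X = projected.values
        boundaries = projected.boundaries
        if frame_interval_ns is None:
            frame_interval_ns = projected.frame_interval_ns
    else:
        X = np.asarray(projected, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if frame_interval_ns is None:
        frame_interval_ns = 1.0
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of frames {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=5, random_state=seed)
    labels = km.fit_predict(X)
    model = MicrostateModel(centers=km.cluster_centers_,
                            inertia=float(km.inertia_), seed=seed)
    dtraj = DiscreteTrajectory.from_array(labels, frame_interval_ns, boundaries)
    return model, dtraj


# ---------------------------------------------------------------------------
# counting and estimation
# ---------------------------------------------------------------------------

def count_transitions(dtraj: DiscreteTrajectory, lag: int,
                      mode: str = "sliding") -> CountMatrix:
    """Transition counts at integer lag, never across segment boundaries."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    n = dtraj.n_states
    C = np.zeros((n, n))
    any_pairs = False
    for seg in dtraj.segments:
        if seg.size <= lag:
            continue
        any_pairs = True
        a = seg[:-lag:] if mode == "sliding" else seg[:-lag:lag]
        b = seg[lag:] if mode == "sliding" else seg[lag::lag]
        np.add.at(C, (a, b), 1.0)
    if not any_pairs:
        raise ValueError(f"all segments shorter than lag {lag}")
    return CountMatrix(counts=C, lag_frames=lag,
                       lag_ns=lag * dtraj.frame_interval_ns)


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """States of the largest strongly connected component of the count graph."""
    adj = (counts > 0).astype(int)
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(adj), directed=True, connection="strong")
    sizes = np.bincount(comp, minlength=n_comp)
    # tie-break: component holding the most counts
    if np.sum(sizes == sizes.max()) > 1:
        weights = np.array([counts[comp == c][:, comp == c].sum()
                            for c in range(n_comp)])
        best = int(np.argmax(np.where(sizes == sizes.max(), weights, -1)))
    else:
        best = int(np.argmax(sizes))
    return np.flatnonzero(comp == best)


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 100000):
    """Detailed-balance maximum likelihood via the standard fixed-point
    iteration on the symmetric edge weights x_ij."""
    c_i = C.sum(axis=1)
    X = C + C.T
    X = X / X.sum()
    for _ in range(max_iter):
        x_i = X.sum(axis=1)
        denom = c_i[:, None] / x_i[:, None] + c_i[None, :] / x_i[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            X_new = np.where(C + C.T > 0, (C + C.T) / denom, 0.0)
        X_new = X_new / X_new.sum()
        delta = np.max(np.abs(X_new - X))
        X = X_new
        if delta < tol:
            break
    x_i = X.sum(axis=1)
    T = X / x_i[:, None]
    pi = x_i / x_i.sum()
    return T, pi


def estimate_markov_model(counts: CountMatrix, reversible: bool = True) -> MarkovModel:
    """Maximum-likelihood transition matrix on the largest connected set.

    Non-reversible: row normalization of the counts.  Reversible: detailed-
    balance MLE by fixed-point iteration (converged when the elementwise
    change falls below 1e−12); the stationary law follows in closed form
    from the symmetric edge weights.
    """
    C_full = counts.counts
    active = largest_connected_set(C_full)
    if active.size == 0:
        raise ValueError("empty connected set")
    dropped = C_full.shape[0] - active.size
    if dropped:
        logger.warning("%d microstate(s) outside the largest connected set "
                       "were excluded", dropped)
    C = C_full[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(C)
    else:
        rows = C.sum(axis=1)
        T = C / rows[:, None]
        vals, vecs = np.linalg.eig(T.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, k]))
        pi = pi / pi.sum()
    # clean numerical residue so invariants hold exactly
    T = np.maximum(T, 0.0)
    T = T / T.sum(axis=1, keepdims=True)
    return MarkovModel(T=T, pi=pi, lag_ns=counts.lag_ns,
                       lag_frames=counts.lag_frames, active_set=active,
                       reversible=reversible, counts=C)


# ---------------------------------------------------------------------------
# implied timescales and lag selection
# ---------------------------------------------------------------------------

def implied_timescales(dtraj: DiscreteTrajectory, lags, n_timescales: int = 3,
                       reversible: bool = True):
    """Table of implied timescales tₖ(τ) = −τ/ln λₖ(τ) across lag times.

    Eigenvalues are sorted by modulus (Perron root excluded); complex pairs
    enter through their modulus; non-positive real eigenvalues give NaN.
    Returns a pandas DataFrame indexed by lag (frames) with a ``lag_ns``
    column and one column per timescale (ns).
    """
    import pandas as pd

    rows = []
    for lag in lags:
        model = estimate_markov_model(count_transitions(dtraj, int(lag)),
                                      reversible=reversible)
        ts = model.timescales(n_timescales)
        rows.append([int(lag), lag * dtraj.frame_interval_ns, *ts])
    cols = ["lag_frames", "lag_ns"] + [f"t{i+2}_ns" for i in range(n_timescales)]
    return pd.DataFrame(rows, columns=cols).set_index("lag_frames")


def select_lag(table, tolerance: float = 0.1) -> int:
    """Smallest tabulated lag at which the slowest implied timescale changes
    by less than ``tolerance`` (relative) over the next two tabulated lags.

    Advisory only; falls back to the largest lag with a warning when the
    table never flattens.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 lags to judge convergence")
    t2 = table.iloc[:, 1].to_numpy(float)  # first timescale column (after lag_ns)
    lags = table.index.to_numpy(int)
    for i in range(len(lags) - 2):
        ref = t2[i]
        if not np.isfinite(ref) or ref <= 0:
            continue
        rel = np.abs(t2[i + 1 : i + 3] - ref) / ref
        if np.all(np.isfinite(rel)) and np.all(rel < tolerance):
            return int(lags[i])
    logger.warning("implied timescales never converged within tolerance %.3g; "
                   "returning the largest lag", tolerance)
    return int(lags[-1])


# ---------------------------------------------------------------------------
# PCCA+
# ---------------------------------------------------------------------------

def _pi_orthonormal_eigenvectors(model: MarkovModel, n: int):
    """Leading right eigenvectors of T, real via the π-symmetrized form."""
    pi = model.pi
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * model.T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    vals, vecs = scipy.linalg.eigh(S)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs / sqrt_pi[:, None]
    # normalize sign and scale: first eigenvector is the constant 1
    psi = psi / np.sign(psi[0, 0]) if psi[0, 0] != 0 else psi
    psi[:, 0] = 1.0
    return vals[:n], psi[:, :n]


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of rows of X spanning the simplex (Deuflhard inner-simplex)."""
    m = X.shape[1]
    ortho = X.copy()
    vertices = np.empty(m, dtype=int)
    for j in range(m):
        norms = np.linalg.norm(ortho, axis=1)
        i = int(np.argmax(norms))
        vertices[j] = i
        v = ortho[i] / norms[i]
        ortho = ortho - np.outer(ortho @ v, v)
    return vertices


def _fill_A(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Enforce feasibility: rows of χ = X A sum to 1 and χ ≥ 0."""
    A = A.copy()
    m = A.shape[0]
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    for j in range(m):
        A[0, j] = -(X[:, 1:] @ A[1:, j]).min()
    s = A[0].sum()
    if s <= 0:
        raise RuntimeError("degenerate PCCA+ feasibility normalization")
    return A / s

def _crispness(chi: np.ndarray, pi: np.ndarray) -> float:
    w = pi @ chi
    return float(np.trace((chi.T * pi) @ chi / w[:, None]))


def pcca_plus(model: MarkovModel, n_macro: int, refine: bool = True) -> MacroAssignment:
    """PCCA+ metastable lumping of microstates into ``n_macro`` macrostates.

    Fuzzy memberships come from the inner-simplex construction on the top
    right eigenvectors (π-symmetrized so the spectral problem is real),
    optionally refined by maximizing the crispness criterion
    trace(diag(w)⁻¹ χᵀ diag(π) χ).  The crisp map is the row argmax (lowest
    index on ties); macrostate populations sum the stationary weights of the
    crisp members.
    """
    n = model.n_states
    if not 2 <= n_macro <= n:
        raise ValueError(f"n_macro must be in [2, {n}]")
    vals, X = _pi_orthonormal_eigenvectors(model, n_macro)
    if np.any(vals <= 0):
        raise ValueError(
            f"only {int(np.sum(vals > 0))} positive leading eigenvalues "
            f"(need {n_macro}); spectrum: {np.round(vals, 6).tolist()}")

    vertices = _inner_simplex_vertices(X)
    A0 = np.linalg.inv(X[vertices])
    try:
        A = _fill_A(A0, X)
    except RuntimeError:
        A = A0
    chi = X @ A

    if refine and n_macro < n and n_macro > 1:
        m = n_macro
        pi = model.pi

        def objective(flat):
            B = A.copy()
            B[1:, 1:] = flat.reshape(m - 1, m - 1)
            try:
                B = _fill_A(B, X)
            except RuntimeError:
                return 1e6
            c = X @ B
            if c.min() < -1e-8:
                return 1e6
            return -_crispness(np.clip(c, 0.0, None), pi)

        x0 = A[1:, 1:].ravel()
        best = scipy.optimize.minimize(objective, x0, method="Nelder-Mead",
                                       options={"maxiter": 2000, "xatol": 1e-10,
                                                "fatol": 1e-12})
        if best.fun < -_crispness(np.clip(chi, 0.0, None), pi) + 1e-15:
            B = A.copy()
            B[1:, 1:] = best.x.reshape(m - 1, m - 1)
            try:
                A = _fill_A(B, X)
                chi = X @ A
            except RuntimeError:
                pass

    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)  # argmax takes the lowest index on ties
    # relabel macrostates by first occurrence for determinism
    order = {}
    for c in crisp:
        if int(c) not in order:
            order[int(c)] = len(order)
    if len(order) < n_macro:
        raise ValueError("PCCA+ produced an empty macrostate under the crisp map")
    relabel = np.empty(n_macro, dtype=int)
    for old, new in order.items():
        relabel[old] = new
    crisp = relabel[crisp]
    chi = chi[:, np.argsort(relabel)]
    populations = np.array([model.pi[crisp == j].sum() for j in range(n_macro)])
    return MacroAssignment(chi=chi, crisp=crisp, populations=populations)
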