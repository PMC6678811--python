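"""Transition-path kinetics on an estimated Markov model.

Given a row-stochastic transition matrix T(τ) with stationary distribution
π, this module computes the quantities used to characterize exchange between
metastable conformations:

* forward/backward committors q⁺, q⁻ (linear solves; the backward committor
  on the time-reversed chain T̃ᵢⱼ = πⱼTⱼᵢ/πᵢ, valid for non-reversible T);
* reactive gross flux fᵢⱼ = πᵢ q⁻ᵢ Tᵢⱼ q⁺ⱼ, its net rectification
  fᵢⱼ⁺ = max(0, fᵢⱼ − fⱼᵢ), and the total flux F_ST over the source cut;
* an Eyring-type apparent free-energy barrier
  F*_ST = −k_B·T·ln( (F_ST/(τ·N_total)) · h/(k_B·T) ), i.e. the total flux
  converted to a rate per conformation and compared with the k_BT/h attempt
  frequency;
* mean first-passage times by the linear system m = τ·1 + T·m with m ≡ 0 on
  the sink, aggregated over macrostates with stationary source weights;
* the kinetic network: macrostate nodes weighted by population, directed
  edges carrying the barrier (kcal·mol⁻¹) and the MFPT (µs), plus a
  two-basin partition by single-link merging on the barriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msm import MacroAssignment, MarkovModel

__all__ = [
    "BOLTZMANN_KCAL",
    "PLANCK_KCAL_S",
    "CommittorPair",
    "FluxResult",
    "BarrierResult",
    "MFPTMatrix",
    "KineticNetwork",
    "compute_committors",
    "compute_flux",
    "apparent_free_energy_barrier",
    "compute_mfpt",
    "mfpt_matrix",
    "build_kinetic_network",
]

# CODATA constants converted to kcal/mol conventions
_KB_J = 1.380649e-23          # J/K
_H_JS = 6.62607015e-34        # J s
_NA = 6.02214076e23           # 1/mol
_J_PER_KCAL = 4184.0

BOLTZMANN_KCAL = _KB_J * _NA / _J_PER_KCAL       # kcal mol^-1 K^-1 (= R)
PLANCK_KCAL_S = _H_JS * _NA / _J_PER_KCAL        # kcal mol^-1 s


# ---------------------------------------------------------------------------
# committors
# ---------------------------------------------------------------------------

@dataclass
class CommittorPair:
    q_forward: np.ndarray
    q_backward: np.ndarray
    source: np.ndarray
    sink: np.ndarray

    def __post_init__(self):
        self.q_forward = np.asarray(self.q_forward, dtype=float)
        self.q_backward = np.asarray(self.q_backward, dtype=float)
        self.source = np.asarray(self.source, dtype=int)
        self.sink = np.asarray(self.sink, dtype=int)
        for q in (self.q_forward, self.q_backward):
            if np.any(q < -1e-10) or np.any(q > 1 + 1e-10):
                raise ValueError("committor values must lie in [0, 1]")


def _validate_sets(n: int, source, sink):
    source = np.unique(np.asarray(source, dtype=int))
    sink = np.unique(np.asarray(sink, dtype=int))
    if source.size == 0 or sink.size == 0:
        raise ValueError("source and sink must be non-empty")
    if np.intersect1d(source, sink).size:
        raise ValueError("source and sink must be disjoint")
    if source.max() >= n or sink.max() >= n or source.min() < 0 or sink.min() < 0:
        raise ValueError("source/sink indices outside the active set")
    return source, sink


def _unreachable_states(T: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """States from which no path reaches ``targets`` in the digraph of T."""
    import scipy.sparse
    import scipy.sparse.csgraph

    n = T.shape[0]
    adj = scipy.sparse.csr_matrix((T.T > 0).astype(int))  # reversed edges
    reach = np.zeros(n, dtype=bool)
    order = scipy.sparse.csgraph.breadth_first_order(
        adj, i_start=int(targets[0]), directed=True, return_predecessors=False)
    reach[order] = True
    for t in targets[1:]:
        if not reach[t]:
            order = scipy.sparse.csgraph.breadth_first_order(
                adj, i_start=int(t), directed=True, return_predecessors=False)
            reach[order] = True
    return np.flatnonzero(~reach)


def _committor(T: np.ndarray, source: np.ndarray, sink: np.ndarray) -> np.ndarray:
    """Probability of hitting ``sink`` before ``source`` from each state."""
    n = T.shape[0]
    q = np.zeros(n)
    q[sink] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([source, sink]))
    if interior.size:
        unreachable = _unreachable_states(T, sink)
        bad = np.intersect1d(unreachable, interior)
        if bad.size:
            raise ValueError(
                f"sink unreachable from state(s) {bad.tolist()}; "
                "committor system is singular")
        A = np.eye(interior.size) - T[np.ix_(interior, interior)]
        b = T[np.ix_(interior, sink)].sum(axis=1)
        q[interior] = np.linalg.solve(A, b)
    return np.clip(q, 0.0, 1.0)


def compute_committors(model: MarkovModel, source, sink) -> CommittorPair:
    """Forward and backward committors between disjoint microstate sets.

    q⁺ solves the first-hitting linear system on T; q⁻ solves the analogous
    system on the time-reversed chain, so the result is exact for
    non-reversible models too (for reversible ones, q⁻ = 1 − q⁺).
    """
    source, sink = _validate_sets(model.n_states, source, sink)
    q_plus = _committor(model.T, source, sink)
    T_rev = (model.pi[None, :] * model.T.T) / model.pi[:, None]
    q_minus = _committor(T_rev, source=sink, sink=source)
    return CommittorPair(q_plus, q_minus, source, sink)


# ---------------------------------------------------------------------------
# flux
# ---------------------------------------------------------------------------

@dataclass
class FluxResult:
    gross: np.ndarray        # f_ij = pi_i q-_i T_ij q+_j, zero diagonal
    net: np.ndarray          # max(0, f_ij - f_ji)
    total: float             # F_ST over the source cut (per lag window)
    lag_ns: float
    source: np.ndarray
    sink: np.ndarray

    def __post_init__(self):
        if np.any(self.gross < 0) or np.any(self.net < 0):
            raise ValueError("fluxes must be non-negative")

    def divergence(self) -> np.ndarray:
        """Net-flux divergence per state (zero off S∪T by conservation)."""
        return self.net.sum(axis=1) - self.net.sum(axis=0)

    def total_across_cut(self, cut_set) -> float:
        """Signed net flux across an arbitrary cut containing S, excluding T
        (forward minus backward crossings; equals ``total`` for every such
        cut by flux conservation)."""
        cut = np.unique(np.asarray(cut_set, dtype=int))
        rest = np.setdiff1d(np.arange(self.net.shape[0]), cut)
        fwd = self.net[np.ix_(cut, rest)].sum()
        bwd = self.net[np.ix_(rest, cut)].sum()
        return float(fwd - bwd)


def compute_flux(model: MarkovModel, committors: CommittorPair) -> FluxResult:
    """Reactive gross and net flux and the total source→sink flux F_ST."""
    pi, T = model.pi, model.T
    qp, qm = committors.q_forward, committors.q_backward
    gross = pi[:, None] * qm[:, None] * T * qp[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(gross - gross.T, 0.0)
    src = committors.source
    rest = np.setdiff1d(np.arange(model.n_states), src)
    total = float(net[np.ix_(src, rest)].sum())
    return FluxResult(gross=gross, net=net, total=total, lag_ns=model.lag_ns,
                      source=src, sink=committors.sink)


# ---------------------------------------------------------------------------
# apparent free-energy barrier
# ---------------------------------------------------------------------------

@dataclass
class BarrierResult:
    barrier_kcal_mol: float
    total_flux: float
    lag_ns: float
    n_total: int
    temperature_K: float
    kBT_kcal_mol: float
    planck_kcal_s: float

    @property
    def rate_per_s(self) -> float:
        return self.total_flux / (self.lag_ns * 1e-9 * self.n_total)


def apparent_free_energy_barrier(
    total_flux: float,
    lag_ns: float,
    n_total: int,
    temperature_K: float = 300.0,
) -> BarrierResult:
    """Eyring-type apparent barrier from a total transition-path flux.

    The flux (effective source→sink transitions per lag window, summed over
    all sampled conformations) is converted to a per-conformation rate
    k = F_ST/(τ·N_total) and compared against the k_B·T/h attempt frequency:
    F* = −k_B·T·ln(k·h/(k_B·T)).  An exactly zero flux gives an infinite
    barrier (returned as ``math.inf``).
    """
    if total_flux < 0:
        raise ValueError("total flux must be >= 0")
    if lag_ns <= 0 or n_total <= 0:
        raise ValueError("lag and N_total must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    kBT = BOLTZMANN_KCAL * temperature_K
    if total_flux == 0.0:
        barrier = math.inf
    else:
        rate = total_flux / (lag_ns * 1e-9 * n_total)   # 1/s
        barrier = -kBT * math.log(rate * PLANCK_KCAL_S / kBT)
    return BarrierResult(barrier_kcal_mol=barrier, total_flux=total_flux,
                         lag_ns=lag_ns, n_total=int(n_total),
                         temperature_K=temperature_K, kBT_kcal_mol=kBT,
                         planck_kcal_s=PLANCK_KCAL_S)


# ---------------------------------------------------------------------------
# mean first-passage times
# ---------------------------------------------------------------------------

def _mfpt_solve(T: np.ndarray, lag_ns: float, sink: np.ndarray) -> np.ndarray:
    """Per-state mean first-passage time (ns) into a sink set.

    Solves (I − T_CC)·m = τ·1 on the non-sink states, m ≡ 0 on the sink.
    """
    n = T.shape[0]
    sink = np.unique(np.asarray(sink, dtype=int))
    if sink.size == 0:
        raise ValueError("sink macrostate is empty")
    other = np.setdiff1d(np.arange(n), sink)
    m = np.zeros(n)
    if other.size:
        unreachable = _unreachable_states(T, sink)
        bad = np.intersect1d(unreachable, other)
        if bad.size:
            raise ValueError(f"sink unreachable from state(s) {bad.tolist()}")
        A = np.eye(other.size) - T[np.ix_(other, other)]
        m[other] = np.linalg.solve(A, np.full(other.size, lag_ns))
    return m


def _mfpt_to_sink(model: MarkovModel, sink_micro: np.ndarray) -> np.ndarray:
    return _mfpt_solve(model.T, model.lag_ns, sink_micro)


def compute_mfpt(
    model: MarkovModel,
    source: int,
    sink: int,
    assignment: MacroAssignment,
) -> tuple[float, np.ndarray]:
    """MFPT (µs) from one macrostate to another, with the per-microstate
    first-passage vector (ns).

    The sink is the crisp member set of the sink macrostate; the macrostate
    value averages the per-microstate times with weights pᵢ = πᵢ/Σ_{S}π.
    """
    if source == sink:
        return 0.0, np.zeros(model.n_states)
    sink_micro = assignment.members(sink)
    source_micro = assignment.members(source)
    if source_micro.size == 0:
        raise ValueError(f"source macrostate {source} is empty")
    m = _mfpt_to_sink(model, sink_micro)
    w = model.pi[source_micro]
    p = w / w.sum()
    mfpt_ns = float(p @ m[source_micro])
    return mfpt_ns * 1e-3, m


@dataclass
class MFPTMatrix:
    """Macrostate-to-macrostate MFPT table (µs), row = source, col = sink."""

    values_us: np.ndarray
    micro_vectors_ns: dict

    def __post_init__(self):
        v = np.asarray(self.values_us, dtype=float)
        if np.any(np.diag(v) != 0):
            raise ValueError("MFPT diagonal must be zero")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal MFPTs must be positive")
        self.values_us = v

    @property
    def n_macrostates(self) -> int:
        return self.values_us.shape[0]

    def to_frame(self, labels=None):
        import pandas as pd

        n = self.n_macrostates
        labels = labels or [f"S{i+1}" for i in range(n)]
        return pd.DataFrame(self.values_us, index=labels, columns=labels)


def mfpt_matrix(model: MarkovModel, assignment: MacroAssignment) -> MFPTMatrix:
    """All ordered macrostate pairs; one linear solve per sink macrostate."""
    n = assignment.n_macrostates
    if n < 2:
        raise ValueError("need at least 2 macrostates")
    values = np.zeros((n, n))
    vectors = {}
    for sink in range(n):
        m = _mfpt_to_sink(model, assignment.members(sink))
        vectors[sink] = m
        for source in range(n):
            if source == sink:
                continue
            src = assignment.members(source)
            p = model.pi[src] / model.pi[src].sum()
            values[source, sink] = float(p @ m[src]) * 1e-3
    return MFPTMatrix(values_us=values, micro_vectors_ns=vectors)


# ---------------------------------------------------------------------------
# kinetic network
# ---------------------------------------------------------------------------

@dataclass
class KineticNetwork:
    """Macrostate graph: node populations, edge barriers (kcal/mol) and
    MFPTs (µs), plus a two-basin partition from the barriers."""

    graph: "object"               # networkx.DiGraph
    populations: np.ndarray
    basins: tuple[frozenset, ...]

    def to_json_dict(self) -> dict:
        import networkx as nx

        data = nx.node_link_data(self.graph, edges="edges")
        data["basins"] = [sorted(b) for b in self.basins]
        return data

    @classmethod
    def from_json_dict(cls, data: dict) -> "KineticNetwork":
        import networkx as nx

        basins = tuple(frozenset(b) for b in data.pop("basins", []))
        graph = nx.node_link_graph(data, directed=True, edges="edges")
        pops = np.array([graph.nodes[n]["population"]
                         for n in sorted(graph.nodes)])
        return cls(graph=graph, populations=pops, basins=basins)

    def write_graphml(self, path: str) -> None:
        import networkx as nx

        g = self.graph.copy()
        for _, _, attrs in g.edges(data=True):  # GraphML cannot store inf
            for k, v in list(attrs.items()):
                if isinstance(v, float) and not math.isfinite(v):
                    attrs[k] = 1e308
        nx.write_graphml(g, path)


def _two_basins(n: int, barrier: np.ndarray) -> tuple[frozenset, ...]:
    """Single-link merging on pairwise barriers until two clusters remain."""
    sym = np.minimum(barrier, barrier.T)
    clusters = [{i} for i in range(n)]
    while len(clusters) > 2:
        best = (math.inf, 0, 1)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(sym[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return tuple(frozenset(c) for c in sorted(clusters, key=min))


def build_kinetic_network(
    assignment: MacroAssignment,
    barriers: dict,
    mfpts: MFPTMatrix,
) -> KineticNetwork:
    """Assemble the macrostate transition network.

    ``barriers`` maps ordered macrostate pairs ``(source, sink)`` to
    :class:`BarrierResult`.  Every ordered pair must be present.
    """
    import networkx as nx

    n = assignment.n_macrostates
    missing = [(s, t) for s in range(n) for t in range(n)
               if s != t and (s, t) not in barriers]
    if missing:
        raise ValueError(f"missing barrier entries for pairs: {missing}")
    if mfpts.n_macrostates != n:
        raise ValueError("MFPT matrix size disagrees with the assignment")

    g = nx.DiGraph()
    for i in range(n):
        g.add_node(i, population=float(assignment.populations[i]))
    bmat = np.zeros((n, n))
    for (s, t), res in barriers.items():
        bmat[s, t] = res.barrier_kcal_mol
        g.add_edge(s, t, barrier_kcal_mol=float(res.barrier_kcal_mol),
                   mfpt_us=float(mfpts.values_us[s, t]),
                   total_flux=float(res.total_flux))
    np.fill_diagonal(bmat, math.inf)
    basins = _two_basins(n, bmat) if n >= 2 else (frozenset(range(n)),)
    return KineticNetwork(graph=g, populations=assignment.populations.copy(),
                          basins=basins)
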