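"""Shared fixtures and independent Monte-Carlo oracles.

The oracles here deliberately avoid the package's linear-algebra paths:
hitting probabilities and first-passage times are measured by simulating
ensembles of random walks directly from the transition matrix, so they can
serve as ground truth for the committor/MFPT solvers.
"""

import numpy as np
import pytest

from kinemsm.msm import MarkovModel
from kinemsm.synthetic import stationary_distribution


def make_random_reversible_model(n: int, seed: int, lag_ns: float = 1.0) -> MarkovModel:
    """Random dense reversible chain from symmetric positive edge weights."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W = 0.5 * (W + W.T)
    T = W / W.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    return MarkovModel(T=T, pi=pi, lag_ns=lag_ns, lag_frames=1,
                       active_set=np.arange(n))


def make_random_model(n: int, seed: int, lag_ns: float = 1.0) -> MarkovModel:
    """Random dense (generally non-reversible) irreducible chain."""
    rng = np.random.default_rng(seed)
    T = rng.dirichlet(np.full(n, 0.8), size=n)
    pi = stationary_distribution(T)
    return MarkovModel(T=T, pi=pi, lag_ns=lag_ns, lag_frames=1,
                       active_set=np.arange(n))


def _step_all(T_cum: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    u = rng.random(states.size)
    return (T_cum[states] < u[:, None]).sum(axis=1)


def mc_hitting_probability(T, source, sink, start, n_walks, seed, max_steps=100000):
    """P(hit sink before source | start), by direct simulation."""
    rng = np.random.default_rng(seed)
    T_cum = np.cumsum(T, axis=1)
    T_cum[:, -1] = 1.0
    absorb = np.zeros(T.shape[0], dtype=int)  # 0 free, 1 source, 2 sink
    absorb[np.asarray(source)] = 1
    absorb[np.asarray(sink)] = 2
    states = np.full(n_walks, start, dtype=np.int64)
    outcome = np.full(n_walks, absorb[start], dtype=int)
    active = outcome == 0
    for _ in range(max_steps):
        if not active.any():
            break
        states[active] = _step_all(T_cum, states[active], rng)
        outcome[active] = absorb[states[active]]
        active = outcome == 0
    assert not active.any(), "hitting simulation did not absorb"
    return (outcome == 2).mean()


def mc_first_passage(T, sink, start_states, start_weights, n_walks, seed,
                     lag_ns=1.0, max_steps=200000):
    """Mean and standard error of the first arrival time into ``sink``.

    Walkers start from ``start_states`` with the given weights; times are in
    units of ``lag_ns`` per step.
    """
    rng = np.random.default_rng(seed)
    T_cum = np.cumsum(T, axis=1)
    T_cum[:, -1] = 1.0
    in_sink = np.zeros(T.shape[0], dtype=bool)
    in_sink[np.asarray(sink)] = True
    states = rng.choice(np.asarray(start_states), size=n_walks, p=start_weights)
    steps = np.zeros(n_walks, dtype=np.int64)
    active = ~in_sink[states]
    k = 0
    while active.any():
        k += 1
        if k > max_steps:
            raise AssertionError("first-passage simulation exceeded step cap")
        states[active] = _step_all(T_cum, states[active], rng)
        steps[active] += 1
        active[active] = ~in_sink[states[active]]
    t = steps * lag_ns
    return float(t.mean()), float(t.std(ddof=1) / np.sqrt(n_walks))


@pytest.fixture
def two_state_model():
    """a = 0.1, b = 0.2, lag 1 ns: the closed-form workhorse."""
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    pi = np.array([2.0, 1.0]) / 3.0
    return MarkovModel(T=T, pi=pi, lag_ns=1.0, lag_frames=1,
                       active_set=np.arange(2))


@pytest.fixture
def two_state_assignment():
    from kinemsm.msm import MacroAssignment

    return MacroAssignment(chi=np.eye(2), crisp=np.array([0, 1]),
                           populations=np.array([2.0, 1.0]) / 3.0)
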