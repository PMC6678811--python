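"""Synthetic dynamics with known ground truth.

Every downstream stage of the package (featurization, tICA, clustering,
Markov-model estimation, transition-path kinetics) is validated against data
whose generating process is known exactly.  Three generators are provided:

* :func:`generate_markov_chain` — discrete jump process from an explicit
  row-stochastic matrix; the oracle for committors, fluxes and MFPTs.
* :func:`simulate_brownian_dynamics` — overdamped Langevin motion on an
  analytic 1D multi-well potential; its stationary law is the Boltzmann
  distribution, computable by quadrature.
* :func:`generate_toy_protein_trajectory` — a polyalanine-like backbone whose
  φ/ψ angles switch between hidden conformational states (emulating
  helix–coil exchange of a portal helix), with the hidden path returned as
  ground truth.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .trajectory import Trajectory, element_radius

__all__ = [
    "PotentialSpec",
    "HiddenStateSpec",
    "SyntheticBundle",
    "generate_markov_chain",
    "simulate_brownian_dynamics",
    "build_backbone_trajectory",
    "generate_toy_protein_trajectory",
    "helix_coil_spec",
    "generate_native_reference",
    "boltzmann_populations",
]

# ideal backbone geometry (Å / degrees); only dihedrals matter downstream
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_C_N_CA = 121.7
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_OMEGA = 180.0


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """Analytic 1D potential for Brownian-dynamics test data.

    ``form`` is one of ``harmonic`` (stiffness about ``centers[0]``),
    ``double_well`` (quartic through two centers, barrier height
    ``depths[0]``·kT, optional asymmetry via ``depths[1]``), or
    ``triple_well`` (Gaussian wells of depth ``depths[i]``·kT at ``centers``
    on a weak harmonic confinement).  ``stiffness`` sets the curvature at the
    well bottoms (energy/length²).
    """

    form: str = "double_well"
    depths: tuple[float, ...] = (4.0,)
    centers: tuple[float, ...] = (-1.0, 1.0)
    stiffness: float = 2.0
    kT: float = 1.0
    confinement: float | None = None

    def __post_init__(self):
        if self.form not in ("harmonic", "double_well", "triple_well"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if any(d <= 0 for d in self.depths):
            raise ValueError("well depths must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if len(self.centers) < 1:
            raise ValueError("at least one well center required")
        if self.form == "double_well" and len(self.centers) != 2:
            raise ValueError("double_well needs exactly two centers")

    # -- energy / gradient -------------------------------------------------

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self.stiffness * (x - self.centers[0]) ** 2
        if self.form == "double_well":
            c1, c2 = sorted(self.centers)
            m, a = 0.5 * (c1 + c2), 0.5 * (c2 - c1)
            h = self.depths[0] * self.kT
            u = h * (((x - m) ** 2 - a**2) ** 2) / a**4
            if len(self.depths) > 1:  # asymmetry: right well deeper by (d1-d2)kT
                tilt = (self.depths[0] - self.depths[1]) * self.kT / (c2 - c1)
                u = u + tilt * (x - m)
            return u
        # triple_well: Gaussian wells + confinement
        widths = self._widths()
        kc = self._confinement()
        xbar = float(np.mean(self.centers))
        u = 0.5 * kc * (x - xbar) ** 2
        for d, c, w in zip(self.depths, self.centers, widths):
            u = u - d * self.kT * np.exp(-((x - c) ** 2) / (2 * w**2))
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return self.stiffness * (x - self.centers[0])
        if self.form == "double_well":
            c1, c2 = sorted(self.centers)
            m, a = 0.5 * (c1 + c2), 0.5 * (c2 - c1)
            h = self.depths[0] * self.kT
            g = h * 4.0 * ((x - m) ** 2 - a**2) * (x - m) / a**4
            if len(self.depths) > 1:
                g = g + (self.depths[0] - self.depths[1]) * self.kT / (c2 - c1)
            return g
        widths = self._widths()
        kc = self._confinement()
        xbar = float(np.mean(self.centers))
        g = kc * (x - xbar)
        for d, c, w in zip(self.depths, self.centers, widths):
            g = g + d * self.kT * (x - c) / w**2 * np.exp(-((x - c) ** 2) / (2 * w**2))
        return g

    def _widths(self):
        # Gaussian width chosen so the curvature at each well bottom is ~stiffness
        return [math.sqrt(d * self.kT / self.stiffness) for d in self.depths]

    def _confinement(self):
        return 0.05 * self.stiffness if self.confinement is None else self.confinement

    def domain(self) -> tuple[float, float]:
        lo, hi = min(self.centers), max(self.centers)
        span = max(hi - lo, 1.0)
        pad = span + 4.0 * math.sqrt(self.kT / self.stiffness)
        return lo - pad, hi + pad

    def max_stiffness(self) -> float:
        """Largest curvature |U''| over the thermally accessible region
        (within 20 kT of the global minimum; grid estimate)."""
        lo, hi = self.domain()
        x = np.linspace(lo, hi, 4001)
        u = self.energy(x)
        g = self.gradient(x)
        curv = np.abs(np.gradient(g, x))
        accessible = u <= u.min() + 20.0 * self.kT
        return float(curv[accessible].max())

    def minima(self) -> np.ndarray:
        lo, hi = self.domain()
        x = np.linspace(lo, hi, 8001)
        u = self.energy(x)
        idx = np.flatnonzero((u[1:-1] < u[:-2]) & (u[1:-1] <= u[2:])) + 1
        return x[idx]


def basin_edges(spec: PotentialSpec) -> np.ndarray:
    """Dividing surfaces between wells: local maxima of U between the centers."""
    centers = np.sort(np.asarray(spec.centers, dtype=float))
    edges = []
    for a, b in zip(centers[:-1], centers[1:]):
        x = np.linspace(a, b, 2001)
        edges.append(float(x[np.argmax(spec.energy(x))]))
    return np.asarray(edges)


def boltzmann_populations(spec: PotentialSpec, edges=None) -> np.ndarray:
    """Equilibrium well populations by numerical quadrature of exp(−U/kT)."""
    lo, hi = spec.domain()
    if edges is None:
        edges = basin_edges(spec)
    bounds = [lo, *np.asarray(edges, dtype=float), hi]
    z = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(lambda x: math.exp(-spec.energy(x) / spec.kT), a, b,
                                limit=200)
        z.append(val)
    z = np.asarray(z)
    return z / z.sum()


# ---------------------------------------------------------------------------
# discrete chains
# ---------------------------------------------------------------------------

def _validate_stochastic(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < -tol):
        i = int(np.argwhere(T < -tol)[0][0])
        raise ValueError(f"negative transition probability in row {i}")
    sums = T.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"row {bad[0]} of transition matrix sums to {sums[bad[0]]!r}, not 1"
        )
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a stochastic matrix, normalized to 1."""
    T = _validate_stochastic(T)
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_markov_chain(
    T: np.ndarray,
    n_steps: int,
    start: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` from a stochastic matrix.

    ``start`` is a state index; ``None`` draws the initial state from the
    stationary distribution.  Deterministic given ``seed``.
    """
    T = _validate_stochastic(T)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    if start is None:
        start = int(rng.choice(n, p=stationary_distribution(T)))
    elif not 0 <= start < n:
        raise ValueError(f"start state {start} outside [0, {n})")
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = s = start
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        out[t] = s
    return out


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

def simulate_brownian_dynamics(
    potential: PotentialSpec,
    n_steps: int,
    dt: float = 0.01,
    seed: int = 0,
    x0: float | None = None,
):
    """Overdamped Euler–Maruyama integration on a 1D potential (friction = 1).

    x_{t+1} = x_t − ∇U(x_t)·dt + √(2·kT·dt)·ξ_t.  The long-run histogram
    converges to exp(−U/kT).  Returns a single-column
    :class:`~kinemsm.features.FeatureMatrix` labelled ``x``.
    """
    from .features import FeatureMatrix

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    kmax = potential.max_stiffness()
    if dt * kmax >= 0.1:
        raise ValueError(
            f"dt={dt} unstable for max stiffness {kmax:.3g}; "
            f"use dt < {0.1 / kmax:.3g}"
        )
    rng = np.random.default_rng(seed)
    if x0 is None:
        minima = potential.minima()
        u = potential.energy(minima)
        x0 = float(minima[np.argmin(u)]) if minima.size else float(potential.centers[0])
    noise = rng.standard_normal(n_steps - 1) * math.sqrt(2.0 * potential.kT * dt)
    x = np.empty(n_steps)
    x[0] = xi = float(x0)
    grad = potential.gradient
    for t in range(1, n_steps):
        xi = xi - float(grad(xi)) * dt + noise[t - 1]
        x[t] = xi
    return FeatureMatrix(values=x[:, None], labels=["x"], frame_interval_ns=dt)


# ---------------------------------------------------------------------------
# toy protein backbone
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HiddenStateSpec:
    """Hidden conformational states emitting backbone dihedral angles.

    ``transition_matrix`` governs the hidden path; each state emits φ/ψ from
    a wrapped normal with mean ``(phi, psi)`` degrees and circular spread
    ``sigma`` degrees (0 = deterministic emission).
    """

    transition_matrix: np.ndarray
    phi_means: tuple[float, ...]
    psi_means: tuple[float, ...]
    sigmas: tuple[float, ...]

    def __post_init__(self):
        T = _validate_stochastic(np.asarray(self.transition_matrix, dtype=float), 1e-12)
        object.__setattr__(self, "transition_matrix", T)
        n = T.shape[0]
        if n < 2:
            raise ValueError("need at least 2 hidden states")
        for name, seq in (("phi_means", self.phi_means), ("psi_means", self.psi_means),
                          ("sigmas", self.sigmas)):
            if len(seq) != n:
                raise ValueError(f"{name} must have one entry per hidden state")
        for ang in (*self.phi_means, *self.psi_means):
            if not -180.0 <= ang < 180.0:
                raise ValueError(f"emission mean {ang} outside [-180, 180)")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("emission spreads must be >= 0")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def helix_coil_spec(a: float = 0.02, b: float = 0.02, sigma: float = 12.0) -> HiddenStateSpec:
    """Two-state helix/coil switcher: state 0 α-helical, state 1 extended."""
    T = np.array([[1 - a, a], [b, 1 - b]])
    return HiddenStateSpec(T, phi_means=(-60.0, -135.0), psi_means=(-45.0, 135.0),
                           sigmas=(sigma, sigma))


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place the next atom from three predecessors (vectorized over frames)."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    coef_bc = -bond * np.cos(theta) * np.ones_like(chi)
    coef_m = bond * np.sin(theta) * np.cos(chi)
    coef_n = bond * np.sin(theta) * np.sin(chi)
    return c + coef_bc[..., None] * bc + coef_m[..., None] * m + coef_n[..., None] * n


def _wrap_degrees(x):
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def build_backbone_trajectory(
    phi_deg: np.ndarray,
    psi_deg: np.ndarray,
    frame_interval_ns: float = 1.0,
) -> Trajectory:
    """Ideal-geometry backbone (N, Cα, C per residue) from explicit φ/ψ.

    ``phi_deg`` and ``psi_deg`` have shape (frames, residues); φ of residue
    ``i`` and ψ of residue ``i−1`` set the placement of residue ``i``, so the
    first φ and last ψ columns are ignored (those dihedrals are undefined at
    chain termini).  ω is fixed at 180°.
    """
    phi = np.atleast_2d(np.asarray(phi_deg, dtype=float))
    psi = np.atleast_2d(np.asarray(psi_deg, dtype=float))
    if phi.shape != psi.shape:
        raise ValueError("phi and psi arrays must have the same shape")
    F, n_residues = phi.shape
    if n_residues < 4:
        raise ValueError("need at least 4 residues for defined dihedrals")
    coords = np.empty((F, 3 * n_residues, 3))
    n0 = np.tile(np.array([0.0, 0.0, 0.0]), (F, 1))
    ca0 = np.tile(np.array([_BOND_N_CA, 0.0, 0.0]), (F, 1))
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[:, 0], coords[:, 1], coords[:, 2] = n0, ca0, c0
    for i in range(1, n_residues):
        nm1, cam1, cm1 = coords[:, 3 * i - 3], coords[:, 3 * i - 2], coords[:, 3 * i - 1]
        n_i = _nerf(nm1, cam1, cm1, _BOND_C_N, _ANGLE_CA_C_N, psi[:, i - 1])
        ca_i = _nerf(cam1, cm1, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _nerf(cm1, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi[:, i])
        coords[:, 3 * i], coords[:, 3 * i + 1], coords[:, 3 * i + 2] = n_i, ca_i, c_i

    atom_names = ["N", "CA", "C"] * n_residues
    elements = ["N", "C", "C"] * n_residues
    res_idx = np.repeat(np.arange(n_residues), 3)
    res_names = ["ALA"] * (3 * n_residues)
    radii = np.array([element_radius(e) for e in elements])
    return Trajectory(
        atom_names=atom_names, elements=elements, residue_indices=res_idx,
        residue_names=res_names, radii=radii, xyz=coords,
        frame_interval_ns=frame_interval_ns,
    )


def generate_toy_protein_trajectory(
    spec: HiddenStateSpec,
    n_residues: int = 8,
    n_frames: int = 1000,
    seed: int = 0,
    frame_interval_ns: float = 1.0,
) -> tuple[Trajectory, np.ndarray]:
    """Backbone (N, Cα, C) trajectory driven by a hidden Markov state path.

    All residues share the frame's hidden state, emulating a short helix
    segment that folds and unfolds as a unit.  Returns the trajectory and the
    per-frame hidden-state labels (the ground truth for MSM recovery).
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues for defined dihedrals")
    rng = np.random.default_rng(seed)
    chain_seed = int(rng.integers(0, 2**31 - 1))
    labels = generate_markov_chain(spec.transition_matrix, n_frames, start=0,
                                   seed=chain_seed)
    mu_phi = np.asarray(spec.phi_means)[labels]            # (F,)
    mu_psi = np.asarray(spec.psi_means)[labels]
    sig = np.asarray(spec.sigmas)[labels]
    phi = _wrap_degrees(mu_phi[:, None] + sig[:, None] *
                        rng.standard_normal((n_frames, n_residues)))
    psi = _wrap_degrees(mu_psi[:, None] + sig[:, None] *
                        rng.standard_normal((n_frames, n_residues)))
    traj = build_backbone_trajectory(phi, psi, frame_interval_ns)
    return traj, labels


def generate_native_reference(traj: Trajectory, frame: int = 0, cutoff: float = 4.5):
    """Native-contact reference from one frame: heavy-atom pairs of residues
    separated by > 3 in sequence whose distance is below ``cutoff`` Å."""
    from .features import NativeReference

    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} outside [0, {traj.n_frames})")
    heavy = np.flatnonzero([e.upper() != "H" for e in traj.elements])
    xyz = traj.xyz[frame]
    res = traj.residue_indices
    ii, jj = np.meshgrid(heavy, heavy, indexing="ij")
    mask = (ii < jj) & (np.abs(res[ii] - res[jj]) > 3)
    ii, jj = ii[mask], jj[mask]
    d = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
    keep = d < cutoff
    pairs = np.stack([ii[keep], jj[keep]], axis=1)
    r0 = d[keep]
    if pairs.shape[0] == 0:
        warnings.warn("native reference is empty; Q will be 1.0 by convention")
    return NativeReference(pairs=pairs, r0=r0,
                           residue_pairs=np.stack([res[ii[keep]], res[jj[keep]]], axis=1)
                           if keep.any() else np.empty((0, 2), dtype=int))


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """A generated dataset plus its generating ground truth and seed."""

    seed: int
    ground_truth: dict
    dtraj: np.ndarray | None = None
    features: "object | None" = None  # FeatureMatrix
    trajectory: Trajectory | None = None
    labels: np.ndarray | None = None

    def save(self, out_prefix: str) -> list[str]:
        import json

        from .features import write_feature_csv
        from .trajectory import write_trajectory

        written = []
        if self.dtraj is not None:
            path = f"{out_prefix}_dtraj.txt"
            np.savetxt(path, self.dtraj, fmt="%d")
            written.append(path)
        if self.features is not None:
            path = f"{out_prefix}_features.csv"
            write_feature_csv(self.features, path)
            written.append(path)
        if self.trajectory is not None:
            written.extend(write_trajectory(self.trajectory, out_prefix))
        if self.labels is not None:
            path = f"{out_prefix}_labels.txt"
            np.savetxt(path, self.labels, fmt="%d")
            written.append(path)
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.ground_truth.items()}
        path = f"{out_prefix}_truth.json"
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, **truth}, fh, indent=1)
        written.append(path)
        return written
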