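"""Per-frame and per-residue structural statistics.

Implements the feature layer between raw coordinates and the kinetic model:
backbone φ/ψ dihedrals (the input matrix for tICA), per-residue helicity,
fraction of native contacts Q and its per-residue restriction Qᵢ, backbone
conformational entropy, Shrake–Rupley solvent-accessible surface area,
least-squares RMSD, and inter-group contact probabilities.

Conventions (documented because the underlying literature rarely states
them): dihedrals follow the IUPAC right-handed sign convention, angles are
degrees in [−180, 180) externally; the helical window is φ ∈ (−100°, −30°),
ψ ∈ (−67°, −7°) sustained over ≥ 3 consecutive residues; the soft native
contact function is the logistic 1/(1+exp(β(r − λr⁰))) with β = 5 Å⁻¹,
λ = 1.8; entropies use R = 1.987 cal·mol⁻¹·K⁻¹ over a 2D φ/ψ histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_CAL",
    "FeatureMatrix",
    "NativeReference",
    "ResidueProfile",
    "compute_backbone_dihedrals",
    "backbone_phi_psi",
    "compute_helicity",
    "compute_native_contact_fraction",
    "compute_dihedral_entropy",
    "compute_sasa",
    "compute_rmsd",
    "compute_contact_probability",
    "dihedral_angle",
    "write_feature_csv",
    "read_feature_csv",
]

GAS_CONSTANT_CAL = 1.987204  # cal mol^-1 K^-1

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-67.0, -7.0)
HELIX_MIN_RUN = 3

Q_BETA = 5.0   # Å^-1, logistic steepness
Q_LAMBDA = 1.8  # tolerance factor on the native distance

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Frames × features real matrix with unique labels and a frame interval."""

    values: np.ndarray
    labels: list[str]
    frame_interval_ns: float = 1.0
    boundaries: tuple[int, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D (frames x features)")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per feature column required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("feature labels must be unique")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if np.isnan(self.values).any():
            bad = np.flatnonzero(np.isnan(self.values).any(axis=0))
            logger.warning("dropping %d feature column(s) with undefined values", bad.size)
            keep = np.setdiff1d(np.arange(self.values.shape[1]), bad)
            self.values = self.values[:, keep]
            self.labels = [self.labels[i] for i in keep]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
        self.boundaries = tuple(sorted(int(b) for b in self.boundaries))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def segments(self) -> list[tuple[int, int]]:
        edges = [0, *self.boundaries, self.n_frames]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


@dataclass
class NativeReference:
    """Native contact pairs (atom indices, native distances, residue pairs)."""

    pairs: np.ndarray      # (P, 2) atom indices, i < j
    r0: np.ndarray         # (P,) native distances Å
    residue_pairs: np.ndarray  # (P, 2) residue indices

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=float).reshape(-1)
        self.residue_pairs = np.asarray(self.residue_pairs, dtype=int).reshape(-1, 2)
        if self.pairs.shape[0] != self.r0.shape[0]:
            raise ValueError("pairs and r0 disagree in length")
        if self.pairs.size and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("contact pairs must satisfy i < j")
        if np.any(self.r0 <= 0):
            raise ValueError("native distances must be positive")

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


_PROFILE_BOUNDS = {
    "helicity": (0.0, 1.0),
    "qi": (0.0, 1.0),
    "contact_probability": (0.0, 1.0),
    "entropy": (0.0, np.inf),
    "sasa": (0.0, np.inf),
}


@dataclass
class ResidueProfile:
    """Residue-indexed values of one statistic, with per-run dispersion."""

    statistic: str
    residue_indices: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    unreliable: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.stderr is None:
            self.stderr = np.zeros_like(self.values)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.unreliable is None:
            self.unreliable = np.zeros(self.values.shape, dtype=bool)
        lo, hi = _PROFILE_BOUNDS.get(self.statistic, (-np.inf, np.inf))
        eps = 1e-9
        if np.any(self.values < lo - eps) or np.any(self.values > hi + eps):
            raise ValueError(
                f"{self.statistic} values outside [{lo}, {hi}]: "
                f"range [{self.values.min()}, {self.values.max()}]"
            )
        if np.any(self.stderr < 0):
            raise ValueError("dispersion must be non-negative")

    def mean_over(self, residues) -> float:
        mask = np.isin(self.residue_indices, np.asarray(list(residues)))
        return float(np.mean(self.values[mask]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "residue_index": self.residue_indices,
            "value": self.values,
            "stderr": self.stderr,
            "unreliable": self.unreliable,
        })


def write_feature_csv(fm: FeatureMatrix, path: str) -> None:
    import pandas as pd

    pd.DataFrame(fm.values, columns=fm.labels).to_csv(path, index=False)


def read_feature_csv(path: str, frame_interval_ns: float = 1.0) -> FeatureMatrix:
    import pandas as pd

    df = pd.read_csv(path)
    return FeatureMatrix(values=df.to_numpy(float), labels=list(df.columns),
                         frame_interval_ns=frame_interval_ns)


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3):
    """Torsion p0–p1–p2–p3 in degrees in [−180, 180), IUPAC right-handed.

    Vectorized over leading axes.  Degenerate (collinear) geometries yield
    NaN.  The sign convention is fixed by the example (0,0,0), (1,0,0),
    (1,1,0), (1,1,1) → +90°.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / nb1
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        ang = np.degrees(np.arctan2(y, x))
        norm_v = np.linalg.norm(v, axis=-1)
        norm_w = np.linalg.norm(w, axis=-1)
    bad = (nb1[..., 0] < 1e-10) | (norm_v < 1e-10) | (norm_w < 1e-10)
    ang = np.where(bad, np.nan, ang)
    # map +180 to -180 so the range is [-180, 180)
    return np.where(ang >= 180.0, ang - 360.0, ang)


def _backbone_atom_table(traj: Trajectory) -> dict[int, dict[str, int]]:
    table: dict[int, dict[str, int]] = {}
    for i, (name, ri) in enumerate(zip(traj.atom_names, traj.residue_indices)):
        table.setdefault(int(ri), {})[name] = i
    return table


def backbone_phi_psi(traj: Trajectory):
    """φ and ψ per residue per frame (degrees; NaN where undefined).

    Returns ``(residue_ids, phi, psi)`` with ``phi``/``psi`` of shape
    (frames, n_residues); φ is undefined for the first residue and ψ for the
    last.
    """
    table = _backbone_atom_table(traj)
    res_ids = sorted(table)
    F = traj.n_frames
    R = len(res_ids)
    phi = np.full((F, R), np.nan)
    psi = np.full((F, R), np.nan)
    xyz = traj.xyz
    n_degenerate = 0
    for k, ri in enumerate(res_ids):
        atoms = table[ri]
        prev_atoms = table.get(ri - 1, {})
        next_atoms = table.get(ri + 1, {})
        if all(n in atoms for n in ("N", "CA", "C")):
            if "C" in prev_atoms:
                phi[:, k] = dihedral_angle(
                    xyz[:, prev_atoms["C"]], xyz[:, atoms["N"]],
                    xyz[:, atoms["CA"]], xyz[:, atoms["C"]])
            if "N" in next_atoms:
                psi[:, k] = dihedral_angle(
                    xyz[:, atoms["N"]], xyz[:, atoms["CA"]],
                    xyz[:, atoms["C"]], xyz[:, next_atoms["N"]])
            n_degenerate += int(np.isnan(phi[:, k]).sum() if "C" in prev_atoms else 0)
    if n_degenerate:
        logger.warning("%d dihedral evaluations degenerate (collinear atoms)",
                       n_degenerate)
    return np.asarray(res_ids), phi, psi


def compute_backbone_dihedrals(traj: Trajectory, encoding: str = "sincos") -> FeatureMatrix:
    """Dihedral feature matrix over interior residues (those with both φ and ψ).

    ``encoding='angles'`` gives degrees; ``'sincos'`` (default, the form fed
    to tICA) maps each angle to its (sin, cos) pair to respect periodicity.
    """
    if encoding not in ("angles", "sincos"):
        raise ValueError("encoding must be 'angles' or 'sincos'")
    res_ids, phi, psi = backbone_phi_psi(traj)
    interior = np.flatnonzero(~np.all(np.isnan(phi), axis=0) &
                              ~np.all(np.isnan(psi), axis=0))
    cols, labels = [], []
    for k in interior:
        rid = res_ids[k]
        for name, arr in (("phi", phi[:, k]), ("psi", psi[:, k])):
            if encoding == "angles":
                cols.append(arr)
                labels.append(f"{name}_res{rid}")
            else:
                cols.append(np.sin(np.deg2rad(arr)))
                labels.append(f"{name}_res{rid}_sin")
                cols.append(np.cos(np.deg2rad(arr)))
                labels.append(f"{name}_res{rid}_cos")
    values = np.stack(cols, axis=1)
    return FeatureMatrix(values=values, labels=labels,
                         frame_interval_ns=traj.frame_interval_ns,
                         boundaries=traj.boundaries)


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------

def _run_length_mask(w: np.ndarray, min_run: int) -> np.ndarray:
    """Positions belonging to a True-run of length >= min_run (along axis 1)."""
    F, R = w.shape
    fwd = np.zeros((F, R), dtype=int)
    for j in range(R):
        prev = fwd[:, j - 1] if j else 0
        fwd[:, j] = np.where(w[:, j], prev + 1, 0)
    bwd = np.zeros((F, R), dtype=int)
    for j in range(R - 1, -1, -1):
        nxt = bwd[:, j + 1] if j < R - 1 else 0
        bwd[:, j] = np.where(w[:, j], nxt + 1, 0)
    runlen = fwd + bwd - 1
    return w & (runlen >= min_run)


def compute_helicity(traj: Trajectory, residues=None) -> ResidueProfile:
    """Per-residue fraction of frames in the helical φ/ψ window.

    A residue counts as helical in a frame only when it sits in a run of at
    least three consecutive residues whose dihedrals all fall inside
    φ ∈ (−100°, −30°), ψ ∈ (−67°, −7°).  Dispersion is the standard error of
    the per-run (source-file) helicity fractions.
    """
    res_ids, phi, psi = backbone_phi_psi(traj)
    defined = ~np.isnan(phi) & ~np.isnan(psi)
    if residues is not None:
        keep = np.isin(res_ids, np.asarray(list(residues)))
    else:
        keep = np.ones(res_ids.size, dtype=bool)
    usable = keep & defined.any(axis=0)
    dropped = np.flatnonzero(keep & ~defined.any(axis=0))
    if dropped.size:
        logger.info("residues without defined phi/psi excluded: %s",
                    res_ids[dropped].tolist())
    in_window = (defined
                 & (phi > HELIX_PHI[0]) & (phi < HELIX_PHI[1])
                 & (psi > HELIX_PSI[0]) & (psi < HELIX_PSI[1]))
    helical = _run_length_mask(in_window, HELIX_MIN_RUN)

    segs = traj.segments()
    per_seg = np.stack([helical[a:b].mean(axis=0) for a, b in segs])  # (S, R)
    values = helical.mean(axis=0)
    if len(segs) > 1:
        stderr = per_seg.std(axis=0, ddof=1) / np.sqrt(len(segs))
    else:
        stderr = np.zeros_like(values)
    return ResidueProfile("helicity", res_ids[usable], values[usable],
                          stderr[usable])


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def compute_native_contact_fraction(
    traj: Trajectory,
    ref: NativeReference,
    mode: str = "soft",
):
    """Per-frame Q and per-residue Qᵢ against a native reference.

    ``hard``: a native pair counts as formed when r < 1.2·r⁰.  ``soft``: each
    pair contributes 1/(1+exp(β(r − λ·r⁰))) with β = 5 Å⁻¹, λ = 1.8.  With an
    empty reference, Q ≡ 1 by convention.
    """
    if mode not in ("soft", "hard"):
        raise ValueError("mode must be 'soft' or 'hard'")
    if ref.n_pairs == 0:
        q = np.ones(traj.n_frames)
        prof = ResidueProfile("qi", np.unique(traj.residue_indices),
                              np.ones(traj.n_residues))
        return q, prof
    if ref.pairs.max() >= traj.n_atoms:
        raise ValueError("native reference atom indices exceed trajectory atoms")
    diff = traj.xyz[:, ref.pairs[:, 0]] - traj.xyz[:, ref.pairs[:, 1]]
    r = np.linalg.norm(diff, axis=2)  # (F, P)
    if mode == "hard":
        formed = (r < 1.2 * ref.r0[None, :]).astype(float)
    else:
        formed = 1.0 / (1.0 + np.exp(Q_BETA * (r - Q_LAMBDA * ref.r0[None, :])))
    q_series = formed.mean(axis=1)

    res_ids = np.unique(traj.residue_indices)
    qi = np.ones(res_ids.size)
    for k, rid in enumerate(res_ids):
        mask = (ref.residue_pairs[:, 0] == rid) | (ref.residue_pairs[:, 1] == rid)
        if mask.any():
            qi[k] = formed[:, mask].mean()
    profile = ResidueProfile("qi", res_ids, np.clip(qi, 0.0, 1.0))
    return q_series, profile


# ---------------------------------------------------------------------------
# dihedral entropy
# ---------------------------------------------------------------------------

def compute_dihedral_entropy(traj: Trajectory, bins_per_angle: int = 24) -> ResidueProfile:
    """Backbone conformational entropy Sᵢ = −R Σ p ln p per residue.

    The (φ, ψ) plane is binned into ``bins_per_angle``² cells over
    [−180, 180)²; empty cells contribute zero.  Units cal·mol⁻¹·K⁻¹.
    Residues with fewer than 10 defined frames are flagged unreliable.
    """
    if bins_per_angle < 2:
        raise ValueError("bins_per_angle must be >= 2")
    res_ids, phi, psi = backbone_phi_psi(traj)
    edges = np.linspace(-180.0, 180.0, bins_per_angle + 1)
    keep = []
    values, unreliable = [], []
    for k in range(res_ids.size):
        mask = ~np.isnan(phi[:, k]) & ~np.isnan(psi[:, k])
        if not mask.any():
            continue
        keep.append(k)
        hist, _, _ = np.histogram2d(phi[mask, k], psi[mask, k], bins=(edges, edges))
        p = hist.ravel() / hist.sum()
        p = p[p > 0]
        values.append(-GAS_CONSTANT_CAL * float(np.sum(p * np.log(p))))
        unreliable.append(int(mask.sum()) < 10)
    return ResidueProfile("entropy", res_ids[keep], np.asarray(values),
                          unreliable=np.asarray(unreliable, dtype=bool),
                          units="cal/(mol K)")


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def compute_sasa(
    traj: Trajectory,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    sidechain_only: bool = False,
) -> ResidueProfile:
    """Shrake–Rupley solvent-accessible surface area, Å², summed per residue.

    Each atom's expanded sphere (radius + probe) is sampled with a
    quasi-uniform point lattice; points strictly inside any other expanded
    sphere are occluded.  ``sidechain_only`` restricts to non-backbone atoms.
    """
    if n_sphere_points < 24:
        raise ValueError("n_sphere_points must be >= 24 for acceptable accuracy")
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if np.any(traj.radii <= 0):
        raise ValueError("all atom radii must be positive")
    points = _sphere_points(n_sphere_points)
    expanded = traj.radii + probe
    if sidechain_only:
        target = np.flatnonzero([n not in _BACKBONE_NAMES for n in traj.atom_names])
    else:
        target = np.arange(traj.n_atoms)

    res_ids = np.unique(traj.residue_indices)
    per_frame = np.zeros((traj.n_frames, res_ids.size))
    rid_pos = {int(r): k for k, r in enumerate(res_ids)}
    for f in range(traj.n_frames):
        xyz = traj.xyz[f]
        for i in target:
            ri = expanded[i]
            d = np.linalg.norm(xyz - xyz[i], axis=1)
            neigh = np.flatnonzero((d < ri + expanded) & (np.arange(traj.n_atoms) != i))
            surf = xyz[i] + ri * points
            if neigh.size:
                dist2 = np.sum(
                    (surf[:, None, :] - xyz[neigh][None, :, :]) ** 2, axis=2)
                free = np.all(dist2 >= (expanded[neigh] ** 2)[None, :] - 1e-12, axis=1)
                frac = free.mean()
            else:
                frac = 1.0
            per_frame[f, rid_pos[int(traj.residue_indices[i])]] += (
                4.0 * np.pi * ri**2 * frac)
    values = per_frame.mean(axis=0)
    if traj.n_frames > 1:
        stderr = per_frame.std(axis=0, ddof=1) / np.sqrt(traj.n_frames)
    else:
        stderr = np.zeros_like(values)
    return ResidueProfile("sasa", res_ids, values, stderr, units="Å^2")


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each frame of P (F,N,3) onto Q (N,3) after optimal
    rigid superposition (Kabsch, batch SVD)."""
    Pc = P - P.mean(axis=1, keepdims=True)
    Qc = Q - Q.mean(axis=0)
    H = np.einsum("fni,nj->fij", Pc, Qc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", U, Vt))
    S_corr = S.copy()
    S_corr[:, -1] *= np.sign(det)
    # rmsd^2 = (|P|^2 + |Q|^2 - 2 tr(S)) / N
    normP = np.sum(Pc**2, axis=(1, 2))
    normQ = np.sum(Qc**2)
    n = P.shape[1]
    msd = (normP + normQ - 2.0 * S_corr.sum(axis=1)) / n
    return np.sqrt(np.maximum(msd, 0.0))


def compute_rmsd(
    traj: Trajectory,
    ref_frame: int = 0,
    selection: np.ndarray | None = None,
    superpose: bool = True,
    ref_xyz: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) to a reference frame (or explicit coordinates).

    With ``superpose`` the optimal least-squares rigid-body superposition is
    applied first; otherwise the raw coordinate RMSD is returned.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    if ref_xyz is None:
        if not 0 <= ref_frame < traj.n_frames:
            raise IndexError(f"reference frame {ref_frame} out of range")
        ref_xyz = traj.xyz[ref_frame, selection]
    else:
        ref_xyz = np.asarray(ref_xyz, dtype=float)
        if ref_xyz.shape != (selection.size, 3):
            raise ValueError("reference coordinates do not match the selection")
    P = traj.xyz[:, selection]
    if superpose:
        if selection.size < 3:
            raise ValueError("superposition needs at least 3 atoms")
        return _kabsch_rmsd(P, ref_xyz)
    diff = P - ref_xyz[None]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


# ---------------------------------------------------------------------------
# contact probability
# ---------------------------------------------------------------------------

def compute_contact_probability(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 4.5,
) -> ResidueProfile:
    """Per residue of ``group_b``: fraction of frames whose minimum heavy-atom
    distance to any ``group_a`` atom is below ``cutoff`` Å."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both atom selections must be non-empty")
    heavy = np.asarray([e.upper() != "H" for e in traj.elements])
    group_a = group_a[heavy[group_a]]
    group_b = group_b[heavy[group_b]]
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("selections contain no heavy atoms")
    diff = traj.xyz[:, group_b][:, :, None, :] - traj.xyz[:, group_a][:, None, :, :]
    dmin_atom = np.sqrt(np.sum(diff**2, axis=3)).min(axis=2)  # (F, |b|)
    res_b = traj.residue_indices[group_b]
    res_ids = np.unique(res_b)
    values = np.empty(res_ids.size)
    for k, rid in enumerate(res_ids):
        cols = np.flatnonzero(res_b == rid)
        values[k] = (dmin_atom[:, cols].min(axis=1) < cutoff).mean()
    return ResidueProfile("contact_probability", res_ids, values)
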