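"""Trajectory container and structural file I/O.

A :class:`Trajectory` is the raw structural input to all feature calculations:
a fixed topology (atom names, elements, residue assignment, van der Waals
radii) plus per-frame Cartesian coordinates in Å and the saving interval in
ns.  Multi-file inputs keep their file boundaries so that time-lagged
statistics never pair frames across independent runs.

File parsing is delegated to :mod:`mdtraj` (PDB topology, DCD/XTC frames);
coordinates are converted from mdtraj's nm to Å on the way in and out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BONDI_RADII",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
]

#: Bondi van der Waals radii, Å, by element symbol.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


def element_radius(element: str) -> float:
    """Bondi radius for an element symbol (case-insensitive; 1.70 Å fallback)."""
    return BONDI_RADII.get(element.strip().upper(), _DEFAULT_RADIUS)


@dataclass
class Trajectory:
    """Topology + coordinates of one or more concatenated simulation runs.

    Parameters
    ----------
    atom_names, elements, residue_names
        Per-atom annotations, length ``n_atoms``.
    residue_indices
        Per-atom residue index (non-decreasing along the chain).
    radii
        Per-atom van der Waals radius in Å.
    xyz
        Coordinates, shape ``(n_frames, n_atoms, 3)``, Å.
    frame_interval_ns
        Simulation time between saved frames.
    boundaries
        Frame indices at which a new source file starts (excluding 0),
        sorted ascending.  Lagged statistics never straddle them.
    """

    atom_names: list[str]
    elements: list[str]
    residue_indices: np.ndarray
    residue_names: list[str]
    radii: np.ndarray
    xyz: np.ndarray
    frame_interval_ns: float = 1.0
    boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must be (frames, atoms, 3), got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue indices must be non-decreasing")
        n = self.xyz.shape[1]
        for name, seq in (
            ("atom_names", self.atom_names),
            ("elements", self.elements),
            ("residue_names", self.residue_names),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} has length {len(seq)}, expected {n}")
        if len(self.residue_indices) != n or len(self.radii) != n:
            raise ValueError("per-atom arrays disagree with atom count")
        self.boundaries = tuple(sorted(int(b) for b in self.boundaries))
        for b in self.boundaries:
            if not 0 < b < self.n_frames:
                raise ValueError(f"boundary {b} outside (0, {self.n_frames})")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_indices))

    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``(start, stop)`` frame ranges of the source files."""
        edges = [0, *self.boundaries, self.n_frames]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def atom_indices_of_residue(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.residue_indices == residue_index)

    def slice_frames(self, frames: np.ndarray | slice) -> "Trajectory":
        return replace(self, xyz=self.xyz[frames], boundaries=())


def _topology_from_mdtraj(top) -> dict:
    atom_names, elements, res_idx, res_names = [], [], [], []
    for atom in top.atoms:
        atom_names.append(atom.name)
        elements.append(atom.element.symbol if atom.element is not None else "C")
        res_idx.append(atom.residue.index)
        res_names.append(atom.residue.name)
    radii = np.array([element_radius(e) for e in elements])
    return dict(
        atom_names=atom_names,
        elements=elements,
        residue_indices=np.array(res_idx),
        residue_names=res_names,
        radii=radii,
    )


def read_trajectory(
    topology_path: str,
    coordinate_paths: str | list[str] | None = None,
    frame_interval_ns: float = 1.0,
) -> Trajectory:
    """Load a PDB topology plus zero or more DCD/XTC coordinate files.

    Multiple coordinate files are concatenated in the given order and their
    boundaries recorded, so downstream lagged statistics treat them as
    independent runs.  With no coordinate file the PDB's own frames are used.
    """
    import mdtraj

    if not os.path.exists(topology_path):
        raise FileNotFoundError(topology_path)
    top = mdtraj.load_topology(topology_path)
    meta = _topology_from_mdtraj(top)
    n_top = top.n_atoms

    if coordinate_paths is None:
        coordinate_paths = []
    elif isinstance(coordinate_paths, (str, os.PathLike)):
        coordinate_paths = [coordinate_paths]

    chunks: list[np.ndarray] = []
    boundaries: list[int] = []
    if not coordinate_paths:
        chunks.append(mdtraj.load(topology_path).xyz * 10.0)
    for path in coordinate_paths:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        try:
            frames = mdtraj.load(str(path), top=top)
        except (ValueError, IOError) as exc:
            msg = str(exc)
            if "atom" in msg.lower():
                raise ValueError(
                    f"atom-count mismatch between topology ({n_top} atoms) "
                    f"and coordinate file {path}: {msg}"
                ) from exc
            ext = os.path.splitext(path)[1]
            raise ValueError(f"could not read {path} as format {ext!r}: {msg}") from exc
        if frames.n_atoms != n_top:
            raise ValueError(
                f"atom-count mismatch: topology has {n_top}, {path} has {frames.n_atoms}"
            )
        if chunks:
            boundaries.append(sum(c.shape[0] for c in chunks))
        chunks.append(frames.xyz * 10.0)  # nm -> Å

    xyz = np.concatenate(chunks, axis=0)
    return Trajectory(
        xyz=xyz,
        frame_interval_ns=frame_interval_ns,
        boundaries=tuple(boundaries),
        **meta,
    )


def to_mdtraj(traj: Trajectory):
    """Convert to an :class:`mdtraj.Trajectory` (Å -> nm)."""
    import mdtraj
    from mdtraj.core import element as md_element

    top = mdtraj.Topology()
    chain = top.add_chain()
    residues = {}
    for i in range(traj.n_atoms):
        ri = int(traj.residue_indices[i])
        if ri not in residues:
            residues[ri] = top.add_residue(traj.residue_names[i], chain, resSeq=ri + 1)
        try:
            elem = md_element.get_by_symbol(traj.elements[i])
        except KeyError:
            elem = md_element.carbon
        top.add_atom(traj.atom_names[i], elem, residues[ri])
    return mdtraj.Trajectory(traj.xyz / 10.0, top)


def write_trajectory(traj: Trajectory, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.pdb`` (topology + first frame) and ``<prefix>.dcd``."""
    md = to_mdtraj(traj)
    pdb_path, dcd_path = f"{out_prefix}.pdb", f"{out_prefix}.dcd"
    md[0].save_pdb(pdb_path)
    md.save_dcd(dcd_path)
    return pdb_path, dcd_path
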