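"""Comparison of crystal structures (Cα RMSD between PDB entries).

The apo and holo crystal forms of heart fatty-acid-binding protein (PDB
entries 3RSW and 3WXQ) are nearly identical — their Cα RMSD after optimal
superposition is ~0.84 Å — which is why kinetic modelling, rather than
static structure comparison, is needed to expose the open intermediates.
This module provides the small amount of machinery for that check: fetching
an entry from the RCSB archive, extracting Cα coordinates with gemmi, and a
Kabsch-superposed RMSD over the residues common to both structures.
"""

from __future__ import annotations

import os
import urllib.request

import numpy as np

__all__ = ["fetch_rcsb", "load_ca_coordinates", "crystal_ca_rmsd"]

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch_rcsb(pdb_id: str, dest_dir: str, timeout: float = 30.0) -> str:
    """Download a PDB entry from the RCSB archive; returns the file path."""
    pdb_id = pdb_id.upper()
    os.makedirs(dest_dir, exist_ok=True)
    path = os.path.join(dest_dir, f"{pdb_id}.pdb")
    if os.path.exists(path):
        return path
    url = _RCSB_URL.format(pdb_id=pdb_id)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    with open(path, "wb") as fh:
        fh.write(data)
    return path


def load_ca_coordinates(pdb_path: str, chain: str | None = None) -> dict[int, np.ndarray]:
    """Cα coordinates (Å) by residue number for one protein chain.

    Uses the first model; ``chain`` defaults to the chain with the most Cα
    atoms.  Alternate locations keep the first occurrence.
    """
    import gemmi

    structure = gemmi.read_structure(str(pdb_path))
    structure.setup_entities()
    model = structure[0]
    best, best_count = None, -1
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        count = sum(1 for res in ch for atom in res if atom.name == "CA")
        if count > best_count:
            best, best_count = ch, count
    if best is None or best_count == 0:
        raise ValueError(f"no Cα atoms found in {pdb_path} (chain={chain!r})")
    out: dict[int, np.ndarray] = {}
    for res in best:
        for atom in res:
            if atom.name == "CA" and res.seqid.num not in out:
                out[res.seqid.num] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return out


def crystal_ca_rmsd(pdb_path_a: str, pdb_path_b: str,
                    chain_a: str | None = None, chain_b: str | None = None) -> float:
    """Cα RMSD (Å) after optimal rigid superposition, over common residues."""
    from .features import _kabsch_rmsd

    ca_a = load_ca_coordinates(pdb_path_a, chain_a)
    ca_b = load_ca_coordinates(pdb_path_b, chain_b)
    common = sorted(set(ca_a) & set(ca_b))
    if len(common) < 3:
        raise ValueError("fewer than 3 common residues between the structures")
    P = np.stack([ca_a[i] for i in common])[None, :, :]
    Q = np.stack([ca_b[i] for i in common])
    return float(_kabsch_rmsd(P, Q)[0])
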