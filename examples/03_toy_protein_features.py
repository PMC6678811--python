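"""Per-residue structural statistics on a helix–coil switching backbone.

Generates a toy 8-residue backbone whose φ/ψ angles jump between a helical
and an extended hidden state, then computes the per-residue helicity,
backbone conformational entropy, fraction of native contacts and
solvent-accessible surface area.
"""

import numpy as np

import kinemsm as km

spec = km.helix_coil_spec(a=0.02, b=0.02, sigma=12.0)
traj, labels = km.generate_toy_protein_trajectory(spec, n_residues=8,
                                                  n_frames=5_000, seed=7)
print(f"{traj.n_frames} frames, {traj.n_atoms} backbone atoms; "
      f"helical-state occupancy (ground truth): {(labels == 0).mean():.3f}")

hel = km.compute_helicity(traj)
print("helicity per residue      :", np.round(hel.values, 3))

ent = km.compute_dihedral_entropy(traj, bins_per_angle=24)
print("entropy (cal/mol/K)       :", np.round(ent.values, 2))

ref = km.generate_native_reference(traj, frame=int(np.flatnonzero(labels == 0)[0]))
q, qi = km.compute_native_contact_fraction(traj, ref, mode="soft")
print(f"native contacts: {ref.n_pairs} pairs; mean Q = {q.mean():.3f}")

sasa = km.compute_sasa(traj.slice_frames(slice(0, 20)), probe=1.4,
                       n_sphere_points=240)
print("SASA per residue (A^2)    :", np.round(sasa.values, 1))

rmsd = km.compute_rmsd(traj, ref_frame=0)
print(f"RMSD to frame 0: mean {rmsd.mean():.2f} A, max {rmsd.max():.2f} A")
print("Helicity tracks the hidden-state occupancy, entropy is highest where "
      "both conformations are visited, and Q drops in the unfolded frames.")
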