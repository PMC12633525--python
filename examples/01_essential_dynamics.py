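"""Essential dynamics of a toy two-state trajectory.

Generates a 20 000-frame trajectory whose atoms jump between two
conformations along a planted collective mode (a slow open/close
transition), runs PCA, and shows that PC1 captures the planted motion.
"""

import numpy as np

from confcouple import compute_pca, displacement_along_pc, select
from confcouple.synthetic import (
    CoupledTrajectoryParams,
    PairSpec,
    generate_coupled_trajectory,
)

params = CoupledTrajectoryParams(
    n_frames=20_000, pairs=[PairSpec(rho=0.8)], seed=7
)
traj, truth = generate_coupled_trajectory(params)

sel = select(traj.topology, "name CA")
pca = compute_pca(traj, sel, align=False)

print(f"trajectory: {traj.n_frames} frames x {traj.n_atoms} atoms")
print(f"PC1 variance {pca.eigenvalues[0]:.3f} A^2 "
      f"(analytic planted value {truth.expected_lambda1:.3f} A^2)")
print(f"PC1 captures {pca.variance_fractions()[0]:.1%} of total variance")
overlap = abs(pca.modes[:, 0] @ truth.mode)
print(f"overlap of PC1 with the planted mode: {overlap:.4f} (1 = perfect)")

profile = displacement_along_pc(pca, 1)
top3 = np.argsort(profile.displacements)[::-1][:3]
print("most displaced atoms along PC1 (residue, displacement):")
for i in top3:
    atom = traj.topology.atoms[sel.indices[i]]
    print(f"  residue {atom.residue_number:3d}  {profile.displacements[i]:.3f} A")
# Atoms with large PC1 displacement are the ones driven by the two-state
# transition, exactly as mobile-loop residues dominate the slow mode of a
# real enzyme.
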