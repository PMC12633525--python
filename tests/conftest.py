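import numpy as np
import pytest

from confcouple import synthetic
from confcouple.trajio import Atom, StructureModel


def make_point_structure(spec):
    """Build a structure from (name, element, resnum, resname, chain, xyz)
    rows; hydrogens inferred from element."""
    atoms = []
    coords = []
    for i, (name, element, resnum, resname, chain, xyz) in enumerate(spec):
        atoms.append(
            Atom(
                atom_index=i,
                atom_name=name,
                element=element,
                residue_number=resnum,
                residue_name=resname,
                chain_id=chain,
                is_heavy=element.upper() not in ("H", "D", "T"),
            )
        )
        coords.append(xyz)
    return StructureModel(atoms, np.asarray(coords, dtype=float))


@pytest.fixture
def toy_protein():
    """3-residue toy: CA+CB per residue plus a PLT ligand with 5 heavy
    atoms and 2 hydrogens."""
    rows = []
    for r in range(1, 4):
        rows.append(("CA", "C", r, "ALA", "A", (float(r), 0.0, 0.0)))
        rows.append(("CB", "C", r, "ALA", "A", (float(r), 1.0, 0.0)))
    for i in range(5):
        rows.append((f"C{i+1}", "C", 10, "PLT", "A", (float(i), 5.0, 0.0)))
    rows.append(("H1", "H", 10, "PLT", "A", (0.0, 6.0, 0.0)))
    rows.append(("H2", "H", 10, "PLT", "A", (1.0, 6.0, 0.0)))
    return make_point_structure(rows)


@pytest.fixture(scope="session")
def coupled_traj_rho08():
    """20k-frame trajectory with one pair planted at rho = 0.8 (seed 7)."""
    params = synthetic.CoupledTrajectoryParams(
        n_frames=20_000, pairs=[synthetic.PairSpec(rho=0.8)], seed=7
    )
    return synthetic.generate_coupled_trajectory(params)
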