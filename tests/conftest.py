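import numpy as np
import pytest

from bwsme import (ModelParameters, assign_charges, compute_contacts,
                   partition_into_blocks)
from bwsme.fixtures import (SyntheticBundleSpec, bundle_structure,
                            make_random_toy)
from bwsme.structure_io import Atom, ProteinStructure, Residue


@pytest.fixture(scope="session")
def toy_params():
    return ModelParameters(xi=-60.0, block_size=1)


@pytest.fixture(scope="session")
def toy_inputs():
    """10-residue compact toy with side chains and charges, block size 1."""
    structure = make_random_toy(10, seed=4)
    contacts = compute_contacts(structure)
    charges = assign_charges(structure)
    partition = partition_into_blocks(structure, 1)
    return structure, partition, contacts, charges


@pytest.fixture(scope="session")
def two_helix_inputs():
    """Packed two-helix bundle (24 residues) with inter-helix contacts."""
    spec = SyntheticBundleSpec(n_helices=2, helix_length=12, loop_length=4,
                               packing_radius=3.5, seed=1)
    structure = bundle_structure(spec)
    contacts = compute_contacts(structure)
    charges = assign_charges(structure)
    partition = partition_into_blocks(structure, 4)
    return structure, partition, contacts, charges


def make_stub_chain(n, resname="ALA", ss="helix", spacing=10.0):
    """Minimal chain of well-separated backbone-only residues (no contacts)."""
    residues = []
    for i in range(n):
        x = i * spacing
        atoms = [Atom("N", "N", (x, 0.0, 0.0)),
                 Atom("CA", "C", (x + 1.0, 0.0, 0.0)),
                 Atom("C", "C", (x + 2.0, 0.0, 0.0))]
        residues.append(Residue(index=i + 1, name=resname, author_id=i + 1,
                                atoms=atoms, ss_label=ss))
    return ProteinStructure("A", residues)
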