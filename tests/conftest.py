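from __future__ import annotations

import numpy as np
import pytest

from consdock import synth
from consdock.chem import AROMATIC, Atom, MolecularGraph, ProteinStructure, Residue


@pytest.fixture(scope="session")
def benzoic_acid():
    return synth.gen_toy_ligand("benzoic_acid")


@pytest.fixture(scope="session")
def isoindoline_dione():
    return synth.gen_toy_ligand("isoindoline_dione")


@pytest.fixture(scope="session")
def pocket():
    """Synthetic receptor plus labelled contact/no-contact poses."""
    return synth.gen_receptor_with_pocket(10, 10, seed=11)


def make_benzene_ring(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0), mol_id="benzene"):
    """A bare aromatic C6 ring with ideal hexagonal coordinates."""
    center = np.asarray(center, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    atoms = []
    for k in range(6):
        ang = np.pi / 3 * k
        atoms.append(Atom("C", center + 1.39 * (np.cos(ang) * u + np.sin(ang) * v)))
    bonds = [(k, (k + 1) % 6, AROMATIC) for k in range(6)]
    return MolecularGraph(mol_id, atoms, bonds)


def make_residue(chain, number, name, atom_specs):
    """Residue from (name, element, xyz) triples."""
    return Residue(
        chain, number, name,
        [Atom(el, np.asarray(xyz, float), 0, nm) for nm, el, xyz in atom_specs],
    )


def protein_of(*residues):
    return ProteinStructure(list(residues), source="test fixture")
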