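"""Symmetry-aware pose RMSD against brute-force and RDKit cross-checks."""

from __future__ import annotations

import numpy as np
import pytest

from consdock.chem import AROMATIC, Atom, MolecularGraph, Pose, PoseEnsemble
from consdock._geometry import random_rotation
from consdock.rmsd import (
    find_automorphisms,
    pose_rmsd,
    redock_pass,
    rmsd_matrix,
)

import oracles


def _graph(elements, bonds, coords=None, mol_id="g"):
    atoms = [
        Atom(el, None if coords is None else coords[k])
        for k, el in enumerate(elements)
    ]
    return MolecularGraph(mol_id, atoms, bonds)


def _benzene(coords=None):
    bonds = [(k, (k + 1) % 6, AROMATIC) for k in range(6)]
    if coords is None:
        coords = [
            [np.cos(np.pi / 3 * k) * 1.39, np.sin(np.pi / 3 * k) * 1.39, 0.0]
            for k in range(6)
        ]
    return _graph(["C"] * 6, bonds, coords, "benzene")


def _benzoate(coords=None):
    """Benzoate anion with delocalised (equivalent) carboxylate oxygens."""
    elements = ["C"] * 6 + ["C", "O", "O"]
    bonds = [(k, (k + 1) % 6, AROMATIC) for k in range(6)]
    bonds += [(0, 6, 1), (6, 7, AROMATIC), (6, 8, AROMATIC)]
    if coords is None:
        ring = [
            [np.cos(np.pi / 3 * k) * 1.39, np.sin(np.pi / 3 * k) * 1.39, 0.0]
            for k in range(6)
        ]
        coords = ring + [[2.9, 0.0, 0.0], [3.6, 1.05, 0.0], [3.6, -1.05, 0.0]]
    return _graph(elements, bonds, coords, "benzoate")


# ---------------------------------------------------------------------------
# automorphisms


def test_linear_chain_has_identity_only():
    g = _graph(["C", "C", "O"], [(0, 1, 1), (1, 2, 1)],
               [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
    assert find_automorphisms(g).permutations == [(0, 1, 2)]


def test_benzene_ring_has_twelve_automorphisms():
    auto = find_automorphisms(_benzene())
    expected = oracles.brute_force_automorphisms(
        ["C"] * 6, [(k, (k + 1) % 6, AROMATIC) for k in range(6)]
    )
    assert len(auto.permutations) == 12
    assert auto.permutations == expected


def test_equivalent_carboxylate_oxygens_give_two_automorphisms():
    g = _graph(["C", "O", "O"], [(0, 1, AROMATIC), (0, 2, AROMATIC)],
               [[0, 0, 0], [1.0, 0.7, 0], [1.0, -0.7, 0]])
    auto = find_automorphisms(g)
    expected = oracles.brute_force_automorphisms(
        ["C", "O", "O"], [(0, 1, AROMATIC), (0, 2, AROMATIC)]
    )
    assert len(auto.permutations) == 2
    assert auto.permutations == expected


def test_automorphism_count_cap_raises():
    # central C with four identical unbonded-to-each-other F: 4! permutations
    elements = ["C", "F", "F", "F", "F"]
    bonds = [(0, k, 1) for k in range(1, 5)]
    g = _graph(elements, bonds, [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0]])
    with pytest.raises(ValueError, match="max_count"):
        find_automorphisms(g, max_count=5)


def test_automorphism_set_contains_identity_and_is_closed(benzoic_acid):
    auto = find_automorphisms(benzoic_acid)
    perms = set(auto.permutations)
    n = len(next(iter(perms)))
    assert tuple(range(n)) in perms
    for p in perms:
        for q in perms:
            composed = tuple(p[q[k]] for k in range(n))
            assert composed in perms


# ---------------------------------------------------------------------------
# pose RMSD


def test_pose_rmsd_identity_translation_and_kabsch():
    g = _benzoate()
    assert pose_rmsd(g, g) == pytest.approx(0.0, abs=1e-12)
    moved = g.with_coords(g.coords() + [3.0, 0.0, 0.0])
    assert pose_rmsd(g, moved, superpose=False) == pytest.approx(3.0, abs=1e-9)
    assert pose_rmsd(g, moved, superpose=True) == pytest.approx(0.0, abs=1e-9)


def test_swapped_carboxylate_oxygens_need_symmetry():
    g = _benzoate()
    coords = g.coords().copy()
    coords[[7, 8]] = coords[[8, 7]]  # swap the two equivalent oxygens
    swapped = g.with_coords(coords)
    assert pose_rmsd(g, swapped, symmetry=True) == pytest.approx(0.0, abs=1e-12)
    assert pose_rmsd(g, swapped, symmetry=False) > 0.1


def test_non_isomorphic_graphs_raise():
    a = _graph(["C", "O"], [(0, 1, 1)], [[0, 0, 0], [1.2, 0, 0]])
    b = _graph(["C", "N"], [(0, 1, 1)], [[0, 0, 0], [1.2, 0, 0]])
    with pytest.raises(ValueError, match="isomorphic|element"):
        pose_rmsd(a, b, symmetry=True)
    with pytest.raises(ValueError):
        pose_rmsd(a, b, symmetry=False)


@pytest.mark.parametrize("mol_factory", [_benzene, _benzoate])
def test_symmetry_rmsd_equals_bruteforce_minimum(mol_factory):
    """Symmetry-aware RMSD equals the explicit min over all label-preserving
    permutations on small graphs (random perturbation suite)."""
    g = mol_factory()
    heavy_elements = [a.element for a in g.atoms]
    perms = oracles.brute_force_automorphisms(heavy_elements, g.bonds)
    rng = np.random.default_rng(31)
    for _ in range(10):
        rot = random_rotation(rng)
        other = g.with_coords(
            g.coords() @ rot.T + rng.normal(scale=0.5, size=3)
        )
        got = pose_rmsd(g, other, symmetry=True)
        want = oracles.brute_force_min_rmsd(g.coords(), other.coords(), perms)
        assert got == pytest.approx(want, abs=1e-9)
        assert got <= pose_rmsd(g, other, symmetry=False) + 1e-12
        assert pose_rmsd(g, other, symmetry=True, superpose=True) <= got + 1e-12


def test_symmetry_rmsd_cross_checks_rdkit_best_rms():
    from rdkit.Chem import AllChem, rdMolAlign

    from consdock import io

    g = _benzoate()
    rng = np.random.default_rng(17)
    rot = random_rotation(rng)
    other = g.with_coords(g.coords() @ rot.T + [1.0, -0.5, 0.7])
    ours = pose_rmsd(g, other, symmetry=True, superpose=True)
    ref = rdMolAlign.GetBestRMS(io.to_rdkit(other), io.to_rdkit(g))
    assert ours == pytest.approx(ref, abs=1e-6)


def test_rmsd_symmetry_of_arguments_and_triangle_inequality():
    g = _benzoate()
    rng = np.random.default_rng(3)
    mols = [g.with_coords(g.coords() + rng.normal(scale=1.0, size=(9, 3)))
            for _ in range(3)]
    for a in mols:
        for b in mols:
            assert pose_rmsd(a, b) == pytest.approx(pose_rmsd(b, a), abs=1e-9)
    # plain per-index RMSD (no symmetry, no fit) is a metric
    d = lambda x, y: pose_rmsd(x, y, symmetry=False, superpose=False)
    a, b, c = mols
    assert d(a, c) <= d(a, b) + d(b, c) + 1e-9


# ---------------------------------------------------------------------------
# matrices and redocking


def _ensemble(graphs, programs=None):
    programs = programs or [f"prog{k:02d}" for k in range(len(graphs))]
    return PoseEnsemble(graphs[0].id, [Pose(g, p) for g, p in zip(graphs, programs)])


def test_rmsd_matrix_identical_and_offset_poses():
    g = _benzene()
    mat = rmsd_matrix(_ensemble([g, g, g]))
    assert np.allclose(mat.values, 0.0)
    offset = g.with_coords(g.coords() + [2.0, 0.0, 0.0])
    mat2 = rmsd_matrix(_ensemble([g, offset]))
    assert mat2.values[0, 1] == pytest.approx(2.0, abs=1e-9)


def test_rmsd_matrix_equals_pairwise_recompute():
    g = _benzoate()
    rng = np.random.default_rng(8)
    graphs = [g.with_coords(g.coords() + rng.normal(scale=0.8, size=(9, 3)))
              for _ in range(5)]
    ens = _ensemble(graphs)
    mat = rmsd_matrix(ens)
    for i in range(5):
        for j in range(5):
            assert mat.values[i, j] == pytest.approx(
                pose_rmsd(graphs[i], graphs[j]), abs=1e-9
            )
    assert mat.labels == ens.programs


def test_redock_pass_boundary_inclusive():
    g = _benzene()
    ref = Pose(g, "xray")
    same = Pose(g, "dock")
    at3 = Pose(g.with_coords(g.coords() + [3.0, 0.0, 0.0]), "dock")
    at35 = Pose(g.with_coords(g.coords() + [3.5, 0.0, 0.0]), "dock")
    assert redock_pass(same, ref)
    assert redock_pass(at3, ref)  # <= 3.0 is accepted
    assert not redock_pass(at35, ref)
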