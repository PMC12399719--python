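"""Geometric interaction detectors against exhaustive double-loop oracles."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_benzene_ring, make_residue, protein_of
from consdock.chem import AROMATIC, Atom, MolecularGraph, Pose
from consdock._geometry import random_rotation
from consdock.interactions import (
    HBondCriteria,
    detect_halogen,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi_stack,
    hierarchical_filter,
)
from consdock.reports import StageReport

import oracles


def _carbonyl_ligand(o_pos, mol_id="lig"):
    """C=O probe ligand with its oxygen at a requested position."""
    o = np.asarray(o_pos, float)
    c = o + [0.0, 0.0, 1.23]
    return MolecularGraph(mol_id, [Atom("C", c, 0, "C1"), Atom("O", o, 0, "O1")], [(0, 1, 2)])


def _serine_donor(og, hg):
    return make_residue("A", 50, "SER", [
        ("N", "N", np.asarray(og) + [0.0, -8.0, 0.0]),
        ("CA", "C", np.asarray(og) + [1.0, -8.0, 0.0]),
        ("OG", "O", og),
        ("HG", "H", hg),
    ])


def test_hbond_satisfying_both_criteria():
    # O-H pointing at the carbonyl oxygen: d(O...O)=2.8, angle ~ 165 deg
    og = np.array([0.0, 0.0, 0.0])
    hg = og + [0.0, 0.0, 0.96]
    # acceptor nearly along the O-H axis, slightly tilted for a 165 deg angle
    direction = np.array([np.sin(np.radians(15)), 0.0, np.cos(np.radians(15))])
    acceptor = og + 2.8 * direction
    prot = protein_of(_serine_donor(og, hg))
    pose = Pose(_carbonyl_ligand(acceptor), "test")
    recs = detect_hbonds(pose, prot)
    assert len(recs) == 1
    rec = recs[0]
    assert rec.kind == "hbond" and rec.resnum == 50
    assert rec.distance == pytest.approx(2.8, abs=1e-9)
    assert rec.angle > 120.0


def test_hbond_distance_cap_and_angle_floor():
    og = np.array([0.0, 0.0, 0.0])
    hg = og + [0.0, 0.0, 0.96]
    prot = protein_of(_serine_donor(og, hg))
    # stretched past the cap
    too_far = Pose(_carbonyl_ligand(og + [0.0, 0.0, 3.6]), "t")
    assert detect_hbonds(too_far, prot) == []
    # inside the cap but a bent 100 deg angle at H
    direction = np.array([np.sin(np.radians(80)), 0.0, np.cos(np.radians(80))])
    bent = Pose(_carbonyl_ligand(hg + 2.0 * direction), "t")
    for rec in detect_hbonds(bent, prot):
        assert rec.angle > 120.0  # nothing at 100 deg gets through
    d = np.linalg.norm(hg + 2.0 * direction - og)
    assert d <= 3.5  # the pair was rejected by angle, not distance


def test_hbond_records_match_double_loop_oracle():
    """Randomised many-pair geometries: implementation = exhaustive oracle."""
    rng = np.random.default_rng(99)
    # random ligand: polar atoms with attached H plus bare acceptors
    atoms, bonds = [], []
    for k in range(8):
        x = rng.uniform(-4, 4, size=3)
        el = rng.choice(["N", "O", "C"])
        atoms.append(Atom(el, x))
        if el in ("N", "O") and rng.random() < 0.7:
            h = x + rng.normal(scale=1.0, size=3)
            h = x + (h - x) / np.linalg.norm(h - x) * 0.98
            atoms.append(Atom("H", h))
            bonds.append((len(atoms) - 2, len(atoms) - 1, 1))
    mol = MolecularGraph("random", atoms, bonds)
    residues = []
    for r in range(6):
        base = rng.uniform(-4, 4, size=3)
        specs = [("O", "O", base)]
        if rng.random() < 0.7:
            h = base + rng.normal(scale=1.0, size=3)
            h = base + (h - base) / np.linalg.norm(h - base) * 0.96
            specs.append(("H", "H", h))
        residues.append(make_residue("A", 100 + r, "SER", specs))
    prot = protein_of(*residues)

    got = detect_hbonds(Pose(mol, "t"), prot)
    lig_atoms = [(a.element, a.coords) for a in mol.atoms]
    lig_bonds = [(i, j) for i, j, _ in mol.bonds]
    oracle_res = [
        (r.chain_id, r.number, r.name, [(a.name, a.element, a.coords) for a in r.atoms])
        for r in prot.residues
    ]
    want = oracles.double_loop_hbonds(lig_atoms, lig_bonds, oracle_res)
    got_keys = set()
    for rec in got:
        if rec.detail == "ligand_donor":
            got_keys.add(("lig_donor", *rec.ligand_atoms, rec.chain, rec.resnum, rec.atom_name))
        else:
            got_keys.add(("prot_donor", rec.ligand_atoms[0], rec.chain, rec.resnum, rec.atom_name))
    assert got_keys == want


def _phe_residue(center, normal, number=182):
    ring = make_benzene_ring(center, normal)
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    # order the names arbitrarily around the hexagon; geometry drives detection
    specs = [(names[k], "C", ring.atoms[k].coords) for k in range(6)]
    specs.append(("CB", "C", np.asarray(center) + np.asarray(normal) * 0.0 + [0, 0, -9]))
    return make_residue("A", number, "PHE", specs)


def test_pi_stack_face_edge_and_out_of_range():
    lig = make_benzene_ring((0, 0, 0), (0, 0, 1))
    pose = Pose(lig, "t")
    face = protein_of(_phe_residue((0, 0, 3.8), (0, 0, 1)))
    recs = detect_pi_stack(pose, face)
    assert len(recs) == 1 and recs[0].detail == "face_to_face"
    edge = protein_of(_phe_residue((0, 4.9, 0.0), (0, 1, 0)))
    recs = detect_pi_stack(pose, edge)
    assert len(recs) == 1 and recs[0].detail == "edge_to_face"
    far = protein_of(_phe_residue((0, 0, 7.0), (0, 0, 1)))
    assert detect_pi_stack(pose, far) == []


def test_hydrophobic_contacts_match_oracle_and_threshold():
    rng = np.random.default_rng(55)
    atoms = [Atom("C", rng.uniform(-3, 3, size=3)) for _ in range(6)]
    mol = MolecularGraph("hydro", atoms, [])
    residues = []
    for r, name in enumerate(["LEU", "ILE", "SER", "PHE"]):
        base = rng.uniform(-3, 3, size=3)
        residues.append(make_residue("A", 130 + r, name, [
            ("CA", "C", base), ("CB", "C", base + [1.4, 0, 0]),
            ("CG", "C", base + [2.2, 0.9, 0]),
        ]))
    prot = protein_of(*residues)
    got = {(r.chain, r.resnum) for r in detect_hydrophobic(Pose(mol, "t"), prot)}
    from consdock.interactions import APOLAR_RESIDUES

    oracle_res = [
        (r.chain_id, r.number, r.name, [(a.name, a.element, a.coords) for a in r.atoms])
        for r in prot.residues
    ]
    want = oracles.double_loop_hydrophobic(
        [(a.element, a.coords) for a in mol.atoms], oracle_res, APOLAR_RESIDUES
    )
    assert got == want
    assert all(r.name != "SER" for r in prot.residues if (r.chain_id, r.number) in got)


def test_halogen_bond_angle_gate_and_oracle():
    def chloro_ligand(cl_pos, c_pos):
        return MolecularGraph("halo", [
            Atom("C", np.asarray(c_pos, float), 0, "C1"),
            Atom("Cl", np.asarray(cl_pos, float), 0, "CL1"),
        ], [(0, 1, 1)])

    acceptor = make_residue("A", 139, "ARG", [("NH1", "N", [0.0, 0.0, 0.0])])
    prot = protein_of(acceptor)
    # C-Cl...N nearly linear (170 deg) at 3.2 A
    cl = np.array([0.0, 0.0, 3.2])
    c_linear = cl + 1.79 * np.array([np.sin(np.radians(10)), 0, np.cos(np.radians(10))])
    assert len(detect_halogen(Pose(chloro_ligand(cl, c_linear), "t"), prot)) == 1
    # bent sigma-hole geometry (120 deg) is rejected
    c_bent = cl + 1.79 * np.array([np.sin(np.radians(60)), 0, np.cos(np.radians(60))])
    assert detect_halogen(Pose(chloro_ligand(cl, c_bent), "t"), prot) == []

    rng = np.random.default_rng(77)
    for _ in range(5):
        cl = rng.uniform(-1, 1, size=3) + [0, 0, 3.0]
        c = cl + rng.normal(size=3)
        c = cl + (c - cl) / np.linalg.norm(c - cl) * 1.79
        mol = chloro_ligand(cl, c)
        got = {(r.ligand_atoms[1], r.chain, r.resnum, r.atom_name)
               for r in detect_halogen(Pose(mol, "t"), prot)}
        want = oracles.double_loop_halogen(
            [(a.element, a.coords) for a in mol.atoms],
            [(i, j) for i, j, _ in mol.bonds],
            [("A", 139, "ARG", [("NH1", "N", np.array([0.0, 0.0, 0.0]))])],
        )
        assert got == want


def test_detectors_are_rigid_transform_invariant(pocket):
    """A common rigid transform of the whole complex changes nothing."""
    protein, poses = pocket
    pose = poses[0][0]
    rng = np.random.default_rng(2)
    rot = random_rotation(rng)
    shift = np.array([3.0, -7.0, 11.0])
    prot_t = protein.with_coords(protein.coords() @ rot.T + shift)
    pose_t = Pose(pose.ligand.with_coords(pose.ligand.coords() @ rot.T + shift),
                  pose.program)
    before = detect_hbonds(pose, protein)
    after = detect_hbonds(pose_t, prot_t)
    assert len(before) == len(after) >= 1
    for b, a in zip(before, after):
        assert b.residue_key == a.residue_key
        assert a.distance == pytest.approx(b.distance, abs=1e-6)
        assert a.angle == pytest.approx(b.angle, abs=1e-6)


def test_emitted_records_recheck_their_criteria(pocket):
    protein, poses = pocket
    criteria = HBondCriteria()
    for pose, _ in poses:
        for rec in detect_hbonds(pose, protein, criteria):
            assert rec.distance <= criteria.d_max
            assert rec.angle > criteria.angle_min


def test_hierarchical_filter_planted_truth_and_monotonicity(pocket):
    protein, labelled = pocket
    poses = {f"c{k:03d}": pose for k, (pose, _) in enumerate(labelled)}
    truth = {f"c{k:03d}" for k, (_, is_contact) in enumerate(labelled) if is_contact}
    reports, survivors = hierarchical_filter([("stage1", poses)], protein)
    assert survivors[0] == truth
    assert reports[0].n_out == len(truth)
    # second stage fed from the survivors shrinks monotonically
    stage2 = {cid: poses[cid] for cid in sorted(truth)}
    reports, survivors = hierarchical_filter(
        [("stage1", poses), ("stage2", stage2)], protein
    )
    assert survivors[1] <= survivors[0]
    assert reports[1].n_initial == len(poses)


def test_hierarchical_filter_rejects_pipeline_ordering_violation(pocket):
    protein, labelled = pocket
    poses = {f"c{k:03d}": pose for k, (pose, _) in enumerate(labelled)}
    bad_stage2 = {"brand_new": labelled[0][0]}
    with pytest.raises(ValueError, match="absent"):
        hierarchical_filter([("s1", poses), ("s2", bad_stage2)], protein)


def test_hierarchical_filter_empty_survivors_residual_zero(pocket):
    protein, labelled = pocket
    only_far = {f"c{k}": pose for k, (pose, contact) in enumerate(labelled) if not contact}
    reports, survivors = hierarchical_filter([("s1", only_far)], protein)
    assert survivors[0] == set()
    assert reports[0].residual_pct_rounded == 0.0


def test_stage_report_validation():
    with pytest.raises(ValueError):
        StageReport("s", 5, 6, 10)
    with pytest.raises(ValueError):
        StageReport("s", 5, 2, 0)
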