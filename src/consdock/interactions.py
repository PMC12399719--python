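"""Geometric protein-ligand interaction detection and the hierarchical filter.

Hydrogen bonds follow the standard geometric definition: donor-acceptor
heavy-atom distance below a cap (default 3.5 A, inclusive) and a D-H...A
angle measured at the hydrogen above a floor (default 120 deg, exclusive).
Donors are N/O (and thiol S) bearing an explicit hydrogen; acceptors are
N/O/S.  No energy model and no charge-dependent special cases.

The hierarchical filter retains, stage by stage, the compounds whose
top-ranked pose hydrogen-bonds to at least one required residue (by default
the catalytic cysteines 313/314), and books per-stage residual percentages
against the first stage's input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from ._geometry import angle_deg
from .chem import MolecularGraph, Pose, ProteinStructure, Residue
from .reports import StageReport

log = logging.getLogger(__name__)

_ACCEPTOR_ELEMENTS = {"N", "O", "S"}
_HALOGENS = {"Cl", "Br", "I"}

#: Residues whose side-chain carbons count as apolar contact partners.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# ligand signatures already warned about donor-less N/O/S atoms (avoid spam)
_warned_donorless: set[tuple[int, int]] = set()

#: Aromatic side-chain ring atom names.
_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
}


@dataclass
class HBondCriteria:
    """Distance cap (inclusive) and angle floor (exclusive) for H-bonds."""

    d_max: float = 3.5
    angle_min: float = 120.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0.0 < self.angle_min < 180.0):
            raise ValueError("angle_min must be in (0, 180)")


@dataclass
class InteractionRecord:
    """One detected contact between a ligand pose and a protein residue."""

    kind: str  # hbond | pi_stack | hydrophobic | halogen
    ligand_atoms: tuple[int, ...]
    chain: str
    resnum: int
    resname: str
    atom_name: str
    distance: float
    angle: Optional[float] = None
    detail: str = ""

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.resnum)

    @property
    def occupancy_key(self) -> tuple[str, str, int]:
        return (self.kind, self.chain, self.resnum)


# ---------------------------------------------------------------------------
# donor / acceptor typing


def _ligand_donors(mol: MolecularGraph) -> list[tuple[int, int]]:
    """(heavy donor index, attached H index) pairs on the ligand."""
    adj = mol.neighbors()
    out = []
    for i, a in enumerate(mol.atoms):
        if a.element not in _ACCEPTOR_ELEMENTS:
            continue
        hs = [j for j in adj[i] if mol.atoms[j].element == "H"]
        for h in hs:
            out.append((i, h))
    return out


def _ligand_acceptors(mol: MolecularGraph) -> list[int]:
    return [i for i, a in enumerate(mol.atoms) if a.element in _ACCEPTOR_ELEMENTS]


def _protein_donors(res: Residue) -> list[tuple[int, int]]:
    """(heavy, H) index pairs within a residue; H attachment by distance."""
    out = []
    skipped = 0
    for i, a in enumerate(res.atoms):
        if a.element not in _ACCEPTOR_ELEMENTS or a.coords is None:
            continue
        attached = []
        for j, h in enumerate(res.atoms):
            if h.element == "H" and h.coords is not None:
                if np.linalg.norm(h.coords - a.coords) <= 1.35:
                    attached.append(j)
        if attached:
            out.extend((i, j) for j in attached)
    return out


def _protein_acceptors(res: Residue) -> list[int]:
    return [i for i, a in enumerate(res.atoms)
            if a.element in _ACCEPTOR_ELEMENTS and a.coords is not None]


def _residues_in_scope(protein: ProteinStructure,
                       residue_filter: Optional[Iterable[tuple[str, int]]]) -> list[Residue]:
    if residue_filter is None:
        return protein.residues
    keys = set(residue_filter)
    return [r for r in protein.residues if (r.chain_id, r.number) in keys]


# ---------------------------------------------------------------------------
# detectors


def detect_hbonds(
    pose: Pose,
    protein: ProteinStructure,
    criteria: HBondCriteria = HBondCriteria(),
    residue_filter: Optional[Iterable[tuple[str, int]]] = None,
) -> list[InteractionRecord]:
    """All geometric H-bonds between a pose and (a subset of) the protein.

    Both directions are scanned: ligand donor to protein acceptor and
    protein donor to ligand acceptor.  Donors without an explicit attached
    hydrogen are skipped (no distance-only fallback) with a logged warning.
    """
    mol = pose.ligand
    records: list[InteractionRecord] = []
    lig_donors = _ligand_donors(mol)
    lig_acceptors = _ligand_acceptors(mol)

    n_donorless = sum(
        1 for i, a in enumerate(mol.atoms)
        if a.element in _ACCEPTOR_ELEMENTS
        and not any(d == i for d, _ in lig_donors)
    )
    signature = (len(mol.atoms), n_donorless)
    if n_donorless and signature not in _warned_donorless:
        _warned_donorless.add(signature)
        log.warning(
            "ligand %s: %d N/O/S atoms carry no explicit hydrogen; skipped as "
            "donors (no distance-only fallback), kept as acceptors",
            mol.id, n_donorless,
        )

    for res in _residues_in_scope(protein, residue_filter):
        # ligand donor -> protein acceptor
        for d_idx, h_idx in lig_donors:
            d, h = mol.atoms[d_idx].coords, mol.atoms[h_idx].coords
            for a_idx in _protein_acceptors(res):
                a = res.atoms[a_idx].coords
                dist = float(np.linalg.norm(d - a))
                if dist > criteria.d_max:
                    continue
                ang = angle_deg(d, h, a)
                if ang > criteria.angle_min:
                    records.append(InteractionRecord(
                        "hbond", (d_idx, h_idx), res.chain_id, res.number,
                        res.name, res.atoms[a_idx].name, dist, ang,
                        detail="ligand_donor",
                    ))
        # protein donor -> ligand acceptor
        for d_idx, h_idx in _protein_donors(res):
            d, h = res.atoms[d_idx].coords, res.atoms[h_idx].coords
            for a_idx in lig_acceptors:
                a = mol.atoms[a_idx].coords
                dist = float(np.linalg.norm(d - a))
                if dist > criteria.d_max:
                    continue
                ang = angle_deg(d, h, a)
                if ang > criteria.angle_min:
                    records.append(InteractionRecord(
                        "hbond", (a_idx,), res.chain_id, res.number,
                        res.name, res.atoms[d_idx].name, dist, ang,
                        detail="protein_donor",
                    ))
    return records


def _ligand_rings(mol: MolecularGraph) -> list[tuple[int, ...]]:
    """Aromatic rings read off the input aromatic-bond flags."""
    from .chem import AROMATIC

    g = nx.Graph((i, j) for i, j, order in mol.bonds if order == AROMATIC)
    rings = []
    for cyc in nx.cycle_basis(g):
        if 5 <= len(cyc) <= 7:
            rings.append(tuple(cyc))
    return rings


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]  # least-variance direction = ring normal


def detect_pi_stack(
    pose: Pose,
    protein: ProteinStructure,
    d_max: float = 5.5,
    angle_tol: float = 30.0,
    residue_filter: Optional[Iterable[tuple[str, int]]] = None,
) -> list[InteractionRecord]:
    """Aromatic ring stacking: face-to-face or edge-to-face by normal angle."""
    mol = pose.ligand
    records = []
    lig_rings = _ligand_rings(mol)
    for res in _residues_in_scope(protein, residue_filter):
        for names in _RING_ATOMS.get(res.name, ()):
            try:
                res_xyz = np.array([res.atom(n).coords for n in names])
            except KeyError:
                continue
            c_res, n_res = _ring_geometry(res_xyz)
            for ring in lig_rings:
                lig_xyz = np.array([mol.atoms[i].coords for i in ring])
                c_lig, n_lig = _ring_geometry(lig_xyz)
                dist = float(np.linalg.norm(c_lig - c_res))
                if dist > d_max:
                    continue
                cosang = abs(float(np.dot(n_lig, n_res)))
                theta = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
                if theta <= angle_tol:
                    orient = "face_to_face"
                elif 90.0 - angle_tol <= theta <= 90.0:
                    orient = "edge_to_face"
                else:
                    continue
                records.append(InteractionRecord(
                    "pi_stack", ring, res.chain_id, res.number, res.name,
                    names[0], dist, theta, detail=orient,
                ))
    return records


def detect_hydrophobic(
    pose: Pose,
    protein: ProteinStructure,
    d_max: float = 4.5,
    residue_filter: Optional[Iterable[tuple[str, int]]] = None,
) -> list[InteractionRecord]:
    """Ligand-carbon / apolar-side-chain-carbon contacts, one record per residue."""
    mol = pose.ligand
    lig_c = [(i, mol.atoms[i].coords) for i in range(len(mol.atoms))
             if mol.atoms[i].element == "C"]
    records = []
    for res in _residues_in_scope(protein, residue_filter):
        if res.name not in APOLAR_RESIDUES:
            continue
        best = None
        involved: set[int] = set()
        for a in res.atoms:
            if a.element != "C" or a.name in _BACKBONE_NAMES or a.coords is None:
                continue
            for i, x in lig_c:
                dist = float(np.linalg.norm(x - a.coords))
                if dist <= d_max:
                    involved.add(i)
                    if best is None or dist < best[0]:
                        best = (dist, a.name)
        if best is not None:
            records.append(InteractionRecord(
                "hydrophobic", tuple(sorted(involved)), res.chain_id,
                res.number, res.name, best[1], best[0],
            ))
    return records


def detect_halogen(
    pose: Pose,
    protein: ProteinStructure,
    d_max: float = 3.6,
    angle_min: float = 140.0,
    residue_filter: Optional[Iterable[tuple[str, int]]] = None,
) -> list[InteractionRecord]:
    """Halogen bonds: C-X...acceptor with X in {Cl, Br, I} (sigma-hole geometry)."""
    mol = pose.ligand
    adj = mol.neighbors()
    records = []
    xs = []
    for i, a in enumerate(mol.atoms):
        if a.element in _HALOGENS:
            carbons = [j for j in adj[i] if mol.atoms[j].element == "C"]
            if carbons:
                xs.append((i, carbons[0]))
    for res in _residues_in_scope(protein, residue_filter):
        for a_idx in _protein_acceptors(res):
            acc = res.atoms[a_idx].coords
            for x_idx, c_idx in xs:
                x = mol.atoms[x_idx].coords
                c = mol.atoms[c_idx].coords
                dist = float(np.linalg.norm(x - acc))
                if dist > d_max:
                    continue
                ang = angle_deg(c, x, acc)
                if ang >= angle_min:
                    records.append(InteractionRecord(
                        "halogen", (c_idx, x_idx), res.chain_id, res.number,
                        res.name, res.atoms[a_idx].name, dist, ang,
                    ))
    return records


# ---------------------------------------------------------------------------
# hierarchical stage driver


def hierarchical_filter(
    stages: Sequence[tuple[str, dict[str, Pose]]],
    protein: ProteinStructure,
    required_residues: Iterable[tuple[str, int]] = (("A", 313), ("A", 314)),
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[list[StageReport], list[set[str]]]:
    """Run the stagewise H-bond retention filter.

    ``stages`` is an ordered list of ``(stage_name, {compound_id: pose})``,
    each stage supplying one top-ranked pose per still-alive compound.  A
    compound survives a stage iff its pose forms at least one H-bond with a
    required residue.  A compound appearing in stage k+1 that did not
    survive stage k violates the pipeline ordering and raises.
    """
    required = set(required_residues)
    if not stages:
        return [], []
    n_initial = len(stages[0][1])
    reports: list[StageReport] = []
    survivor_sets: list[set[str]] = []
    alive: Optional[set[str]] = None
    for name, poses in stages:
        if alive is not None:
            extra = set(poses) - alive
            if extra:
                raise ValueError(
                    f"stage {name!r} contains compounds absent from the previous "
                    f"stage's survivors: {sorted(extra)[:5]}"
                )
        survivors = {
            cid for cid, pose in poses.items()
            if detect_hbonds(pose, protein, criteria, residue_filter=required)
        }
        reports.append(StageReport(name, len(poses), len(survivors), max(n_initial, 1)))
        survivor_sets.append(survivors)
        alive = survivors
    return reports, survivor_sets
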