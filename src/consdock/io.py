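"""Readers and writers for SDF (V2000), MOL2 (TRIPOS) and PDB.

Parsing is delegated to RDKit (SDF/MOL2/SMARTS) and Biopython (PDB); this
module converts to and from the package's own :mod:`consdock.chem` types.
Sanitisation is switched off everywhere so that input aromatic flags and
explicit hydrogens pass through untouched.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .chem import (
    AROMATIC,
    Atom,
    MolecularGraph,
    ParseError,
    ProteinStructure,
    Residue,
    Trajectory,
)

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}
_ORDER_TO_RDKIT = {v: k for k, v in _ORDER_FROM_RDKIT.items()}


# ---------------------------------------------------------------------------
# RDKit conversion


def from_rdkit(mol: Chem.Mol, mol_id: Optional[str] = None) -> MolecularGraph:
    """Convert an RDKit molecule (with a conformer if 3D) to a MolecularGraph."""
    conf = mol.GetConformer() if mol.GetNumConformers() else None
    atoms = []
    for a in mol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(a.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(Atom(a.GetSymbol(), coords, a.GetFormalCharge()))
    bonds = []
    for b in mol.GetBonds():
        order = _ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            raise ParseError(f"unsupported bond type {b.GetBondType()}")
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    props = {k: str(v) for k, v in mol.GetPropsAsDict().items() if not k.startswith("_")}
    if mol_id is None:
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    return MolecularGraph(mol_id, atoms, bonds, props)


def to_rdkit(graph: MolecularGraph, with_coords: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule.

    Explicit-H semantics are preserved: no implicit hydrogens are added and
    atoms incident to aromatic bonds get their aromatic flag set so SMARTS
    aromaticity queries behave as expected.
    """
    rw = Chem.RWMol()
    for a in graph.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j, order in graph.bonds:
        rw.AddBond(i, j, _ORDER_TO_RDKIT[order])
        if order == AROMATIC:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    if with_coords and all(a.coords is not None for a in graph.atoms):
        conf = Chem.Conformer(len(graph.atoms))
        for k, a in enumerate(graph.atoms):
            conf.SetAtomPosition(k, tuple(float(x) for x in a.coords))
        mol.AddConformer(conf)
    if graph.id:
        mol.SetProp("_Name", graph.id)
    for k, v in graph.properties.items():
        mol.SetProp(k, v)
    return mol


# ---------------------------------------------------------------------------
# SDF


def read_sdf(path: Union[str, Path]) -> list[MolecularGraph]:
    """Read an SDF (V2000) file; one MolecularGraph per record."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.read_text().strip() == "":
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    graphs = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"malformed SDF record at index {i} in {path}")
        graphs.append(from_rdkit(mol, mol_id=None))
    return graphs


def write_sdf(graphs: Sequence[MolecularGraph], path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for g in graphs:
            mol = to_rdkit(g)
            block = Chem.MolToMolBlock(mol, kekulize=False)
            fh.write(block)
            for k, v in g.properties.items():
                fh.write(f">  <{k}>\n{v}\n\n")
            fh.write("$$$$\n")


# ---------------------------------------------------------------------------
# MOL2 (TRIPOS dialect only)


def read_mol2(path: Union[str, Path]) -> MolecularGraph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError(f"could not parse TRIPOS MOL2 file {path}")
    return from_rdkit(mol, mol_id=None)


# ---------------------------------------------------------------------------
# SMARTS substructure matching


def match_substructure(graph: MolecularGraph, pattern: str) -> list[tuple[int, ...]]:
    """All distinct embeddings of a SMARTS pattern; empty list when none."""
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
    mol = to_rdkit(graph, with_coords=False)
    return [tuple(m) for m in mol.GetSubstructMatches(query, uniquify=True)]


# ---------------------------------------------------------------------------
# PDB (via Biopython)

_PDB_ELEMENT_FIX = {"": None}


def _element_of(bp_atom) -> str:
    el = (bp_atom.element or "").strip()
    if not el:
        # fall back on the atom name's first letter
        el = "".join(c for c in bp_atom.get_name() if c.isalpha())[:1]
    return el.capitalize() if len(el) > 1 else el.upper()


def _select_altloc(bp_atom):
    """For a disordered atom keep the highest-occupancy alternate, logged."""
    from Bio.PDB.Atom import DisorderedAtom

    if isinstance(bp_atom, DisorderedAtom):
        children = list(bp_atom.disordered_get_list())
        best = max(children, key=lambda c: (c.get_occupancy() or 0.0))
        log.warning(
            "altloc on atom %s: keeping %r (occupancy %.2f) of %d alternates",
            bp_atom.get_name(),
            best.get_altloc(),
            best.get_occupancy() or 0.0,
            len(children),
        )
        return best
    return bp_atom


def _model_to_structures(model, source: str) -> tuple[ProteinStructure, list[MolecularGraph]]:
    residues: list[Residue] = []
    ligands: list[MolecularGraph] = []
    for chain in model:
        for res in chain:
            hetfield, resnum, _ = res.get_id()
            atoms = []
            for bp_atom in res:  # packed atoms: altloc groups arrive as one entry
                bp_atom = _select_altloc(bp_atom)
                xyz = bp_atom.get_coord()
                if xyz is None or not np.all(np.isfinite(xyz)):
                    raise ParseError(f"missing coordinates on atom {bp_atom.get_full_id()}")
                atoms.append(
                    Atom(_element_of(bp_atom), np.asarray(xyz, dtype=float), 0, bp_atom.get_name())
                )
            if hetfield.strip() and hetfield != "W":
                # HETATM record (not water): expose as a ligand graph (no bonds —
                # PDB connectivity is not inferred)
                ligands.append(
                    MolecularGraph(
                        f"{res.get_resname()}_{chain.id}_{resnum}",
                        atoms,
                        [],
                        {"resname": res.get_resname(), "chain": chain.id, "resnum": str(resnum)},
                    )
                )
            else:
                residues.append(Residue(chain.id, int(resnum), res.get_resname(), atoms))
    return ProteinStructure(residues, source), ligands


def read_pdb(path: Union[str, Path]) -> tuple[ProteinStructure, list[MolecularGraph]]:
    """Read the first MODEL of a PDB file.

    Returns the protein (chain/residue hierarchy, author numbering) and any
    HETATM groups (excluding waters) as bond-less MolecularGraphs.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ParseError(f"no MODEL in {path}")
    return _model_to_structures(models[0], str(path))


def read_pdb_trajectory(
    path: Union[str, Path],
    ligand_resnames: Sequence[str] = (),
    frame_interval: float = 200.0,
) -> Trajectory:
    """Read a multi-MODEL PDB as a Trajectory (one frame per MODEL).

    Residues whose name is in ``ligand_resnames`` (or any non-water HETATM
    group) form the ligand; everything else is protein.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ParseError(f"no MODEL in {path}")

    def split(model):
        prot_atoms, lig_atoms = [], []
        prot_meta: list[tuple[str, int, str]] = []
        lig_elements: list[tuple[str, str]] = []
        for chain in model:
            for res in chain:
                hetfield, resnum, _ = res.get_id()
                is_lig = res.get_resname() in ligand_resnames or (
                    hetfield.strip() and hetfield != "W"
                )
                for bp_atom in res:
                    bp_atom = _select_altloc(bp_atom)
                    entry = (
                        _element_of(bp_atom),
                        np.asarray(bp_atom.get_coord(), dtype=float),
                        bp_atom.get_name(),
                    )
                    if is_lig:
                        lig_atoms.append(entry)
                        lig_elements.append((entry[0], entry[2]))
                    else:
                        prot_atoms.append(entry)
                        prot_meta.append((chain.id, int(resnum), res.get_resname()))
        return prot_atoms, prot_meta, lig_atoms

    prot_atoms0, prot_meta0, lig_atoms0 = split(models[0])

    residues: list[Residue] = []
    current: Optional[tuple[str, int, str]] = None
    for (el, xyz, name), meta in zip(prot_atoms0, prot_meta0):
        if meta != current:
            residues.append(Residue(meta[0], meta[1], meta[2], []))
            current = meta
        residues[-1].atoms.append(Atom(el, xyz, 0, name))
    protein = ProteinStructure(residues, str(path))

    ligand = None
    if lig_atoms0:
        ligand = MolecularGraph(
            "ligand", [Atom(el, xyz, 0, name) for el, xyz, name in lig_atoms0], []
        )

    frames = []
    for m in models:
        pa, _, la = split(m)
        if len(pa) != len(prot_atoms0) or len(la) != len(lig_atoms0):
            raise ParseError("MODELs do not share a common topology")
        frames.append(np.array([x for _, x, _ in pa] + [x for _, x, _ in la]))
    return Trajectory(protein, ligand, np.array(frames), frame_interval)


def _format_pdb_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
                     xyz: np.ndarray, element: str, het: bool) -> str:
    record = "HETATM" if het else "ATOM  "
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {nm:<4.4s} {resname:<3.3s} {chain:1.1s}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{element:>2.2s}\n"
    )


def write_pdb_trajectory(traj: Trajectory, path: Union[str, Path],
                         ligand_resname: str = "LIG") -> None:
    """Write a Trajectory as a multi-MODEL PDB file."""
    path = Path(path)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            k = 0
            coords = traj.frames[f]
            for res in traj.protein.residues:
                for a in res.atoms:
                    fh.write(
                        _format_pdb_atom(
                            serial, a.name or a.element, res.name, res.chain_id,
                            res.number, coords[k], a.element, het=False,
                        )
                    )
                    serial += 1
                    k += 1
            if traj.ligand is not None:
                for i, a in enumerate(traj.ligand.atoms):
                    fh.write(
                        _format_pdb_atom(
                            serial, a.name or f"{a.element}{i + 1}", ligand_resname, "X",
                            1, coords[k], a.element, het=True,
                        )
                    )
                    serial += 1
                    k += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_protein_pdb(protein: ProteinStructure, path: Union[str, Path]) -> None:
    """Write a single-model protein PDB file."""
    traj = Trajectory(protein, None, protein.coords()[None, :, :], 1.0)
    write_pdb_trajectory(traj, path)
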