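"""Core chemical data types shared by every pipeline stage.

Conventions
-----------
* Coordinates are in Angstrom throughout.
* Atom indices are 0-based internally; 1-based only in rendered reports.
* Hydrogens are read when present and never added implicitly.
* Aromaticity is taken from input flags (SDF bond type 4, MOL2 ``ar``);
  no re-perception is done, which keeps parity across formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: Bond-order code for aromatic bonds (SDF V2000 convention).
AROMATIC = 4

_VALID_ORDERS = {1, 2, 3, AROMATIC}

# Periodic table subset is deliberately not hard-coded: element validity is
# checked against RDKit's periodic table at construction time.
from rdkit import Chem as _Chem

_PT = _Chem.GetPeriodicTable()


class ParseError(ValueError):
    """A structure file could not be parsed."""


def _is_valid_element(symbol: str) -> bool:
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


@dataclass
class Atom:
    """One atom: element symbol, optional 3D position, charge and name."""

    element: str
    coords: Optional[np.ndarray] = None
    formal_charge: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not _is_valid_element(self.element):
            raise ValueError(f"invalid element symbol: {self.element!r}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,):
                raise ValueError("coords must be a 3-vector")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("coords must be finite")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class MolecularGraph:
    """A ligand: ordered atoms, bonds with order labels, free-text properties.

    Bonds are ``(i, j, order)`` with ``order`` in {1, 2, 3, AROMATIC}.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i}, {j})")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if order not in _VALID_ORDERS:
                raise ValueError(f"invalid bond order {order} on ({i}, {j})")

    # -- indexing helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array; raises if any atom lacks coords."""
        missing = [i for i, a in enumerate(self.atoms) if a.coords is None]
        if missing:
            raise ValueError(f"atoms without coordinates: {missing[:5]}")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        idx = self.heavy_indices
        missing = [i for i in idx if self.atoms[i].coords is None]
        if missing:
            raise ValueError(f"heavy atoms without coordinates: {missing[:5]}")
        return np.array([self.atoms[i].coords for i in idx], dtype=float)

    def neighbors(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def with_coords(self, coords: np.ndarray, id: Optional[str] = None) -> "MolecularGraph":
        """Copy of this graph with every atom's position replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coords shape must be (n_atoms, 3)")
        atoms = [
            Atom(a.element, coords[k].copy(), a.formal_charge, a.name)
            for k, a in enumerate(self.atoms)
        ]
        return MolecularGraph(id or self.id, atoms, list(self.bonds), dict(self.properties))


@dataclass
class Pose:
    """One docked conformation of a ligand, tagged with its docking program."""

    ligand: MolecularGraph
    program: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.program:
            raise ValueError("pose must carry a non-empty program label")
        for i in self.ligand.heavy_indices:
            if self.ligand.atoms[i].coords is None:
                raise ValueError("pose ligand must have coordinates on all heavy atoms")


@dataclass
class PoseEnsemble:
    """The multi-program pose set of one ligand, the consensus working set."""

    ligand_id: str
    poses: list[Pose]

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def programs(self) -> list[str]:
        return [p.program for p in self.poses]


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom]

    def atom(self, atom_name: str) -> Atom:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        raise KeyError(f"no atom {atom_name!r} in {self.chain_id}:{self.number} {self.name}")


@dataclass
class ProteinStructure:
    """Receptor chains as an ordered residue list (author numbering kept)."""

    residues: list[Residue]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            key = (r.chain_id, r.number)
            if key in seen:
                raise ValueError(f"duplicate residue {key} within a chain")
            seen.add(key)

    def residue(self, chain_id: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.number == number:
                return r
        raise KeyError(f"no residue {chain_id}:{number}")

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        out = []
        for _, a in self.iter_atoms():
            if a.coords is None:
                raise ValueError("protein atom without coordinates")
            out.append(a.coords)
        return np.array(out, dtype=float)

    def with_coords(self, coords: np.ndarray) -> "ProteinStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coords shape must be (n_atoms, 3)")
        k = 0
        residues = []
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.element, coords[k].copy(), a.formal_charge, a.name))
                k += 1
            residues.append(Residue(r.chain_id, r.number, r.name, atoms))
        return ProteinStructure(residues, self.source)


@dataclass
class Trajectory:
    """Frames of a protein-ligand complex sharing one topology.

    The per-frame coordinate array concatenates protein atoms (in residue
    order) followed by ligand atoms; ``frame_interval`` is in picoseconds.
    """

    protein: ProteinStructure
    ligand: Optional[MolecularGraph]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 200.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame coordinates must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_protein_atoms(self) -> int:
        return self.protein.n_atoms

    @property
    def n_atoms(self) -> int:
        return self.n_protein_atoms + (len(self.ligand) if self.ligand is not None else 0)

    def protein_at(self, frame: int) -> ProteinStructure:
        return self.protein.with_coords(self.frames[frame, : self.n_protein_atoms])

    def ligand_at(self, frame: int) -> MolecularGraph:
        if self.ligand is None:
            raise ValueError("trajectory carries no ligand")
        return self.ligand.with_coords(self.frames[frame, self.n_protein_atoms :])

    def ca_indices(self) -> np.ndarray:
        """Global indices of protein alpha-carbon (CA) atoms."""
        idx = []
        k = 0
        for _, a in self.protein.iter_atoms():
            if a.name == "CA" and a.element == "C":
                idx.append(k)
            k += 1
        return np.asarray(idx, dtype=int)

    def ligand_heavy_indices(self) -> np.ndarray:
        if self.ligand is None:
            raise ValueError("trajectory carries no ligand")
        off = self.n_protein_atoms
        return np.asarray([off + i for i in self.ligand.heavy_indices], dtype=int)

    def subsample(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            self.protein, self.ligand, self.frames[::stride], self.frame_interval * stride
        )
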