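"""Synthetic inputs with the statistical structure each pipeline stage assumes.

These generators stand in for the docking engines and the MD package: pose
ensembles with a planted dominant cluster plus outliers, a toy receptor
whose pocket plants hydrogen-bond positives and negatives against the
catalytic cysteines, and trajectories with planted per-interaction
occupancies and Gaussian coordinate noise.  Every generator draws from one
seeded random stream passed in explicitly; no hidden global state.

Planted H-bond geometries use a donor-acceptor distance of 2.8 A and a
D-H...A angle of 160 deg (comfortably inside the 3.5 A / 120 deg criteria);
violations use 4.5 A, so recovery is robust to small coordinate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._geometry import random_rotation
from .chem import (
    Atom,
    MolecularGraph,
    Pose,
    PoseEnsemble,
    ProteinStructure,
    Residue,
    Trajectory,
)

_TOY_SMILES = {
    "benzoic_acid": "OC(=O)c1ccccc1",
    "isoindoline_dione": "O=C1NC(=O)c2ccccc21",
    "n_butyl_isoindoline_benzoate": "CCCCN1C(=O)c2ccc(cc2C1=O)-c1ccc(cc1)C(=O)O",
    "retinoid_like": "CC(C)=CC=CC(C)=CC=CC(C)=CC(O)=O",
}

_EMBED_SEED = 20240917  # fixed: toy geometries are deterministic by design

CONTACT_DISTANCE = 2.8
CONTACT_ANGLE = 160.0
VIOLATION_DISTANCE = 4.5


def gen_toy_ligand(name: str) -> MolecularGraph:
    """A small test ligand with explicit hydrogens and deterministic 3D coords."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from .io import from_rdkit

    if name not in _TOY_SMILES:
        raise ValueError(f"unknown toy ligand {name!r}; choose from {sorted(_TOY_SMILES)}")
    mol = Chem.MolFromSmiles(_TOY_SMILES[name])
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {name}")
    graph = from_rdkit(mol, mol_id=name)
    return graph


# ---------------------------------------------------------------------------
# pose ensembles


@dataclass
class EnsembleSpec:
    """Conditions of one planted multi-program pose ensemble."""

    n_programs: int = 12
    n_consensus: int = 9
    cluster_radius: float = 1.0
    outlier_offset: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_consensus <= self.n_programs):
            raise ValueError("need 1 <= n_consensus <= n_programs")
        if not (0 <= self.cluster_radius < self.outlier_offset):
            raise ValueError("need 0 <= cluster_radius < outlier_offset")


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_pose_ensemble(
    spec: EnsembleSpec,
    base: Union[Pose, MolecularGraph],
) -> tuple[PoseEnsemble, int]:
    """Planted ensemble: a tight consensus cluster plus mutually distant outliers.

    Consensus poses are the base pose under random rigid translations of
    magnitude at most ``cluster_radius / 2`` (so any two are within
    ``cluster_radius`` of each other); each outlier is displaced by at
    least ``outlier_offset``, with magnitudes spaced so outliers are also
    mutually at least ``outlier_offset`` apart.  Returns the ensemble and
    the planted consensus level (= ``n_consensus``, one pose per program).
    """
    rng = np.random.default_rng(spec.seed)
    mol = base.ligand if isinstance(base, Pose) else base
    coords = mol.coords()
    programs = [f"prog{k + 1:02d}" for k in range(spec.n_programs)]
    shifts = []
    for k in range(spec.n_programs):
        if k < spec.n_consensus:
            mag = rng.uniform(0.0, spec.cluster_radius / 2.0)
        else:
            rank = k - spec.n_consensus
            mag = spec.outlier_offset * (rank + 1)
        shifts.append(mag * _unit_vector(rng))
    order = rng.permutation(spec.n_programs)
    poses = [
        Pose(mol.with_coords(coords + shifts[k], id=f"{mol.id}_{programs[k]}"), programs[k])
        for k in order
    ]
    return PoseEnsemble(mol.id, poses), spec.n_consensus


# ---------------------------------------------------------------------------
# toy receptor with a catalytic-cysteine pocket


def _acceptor_position(s: np.ndarray, h: np.ndarray, distance: float,
                       angle: float) -> np.ndarray:
    """Point A with |A - s| = distance and angle(s, h, A) = angle (degrees)."""
    z = s - h
    z_len = float(np.linalg.norm(z))
    z = z / z_len
    # any perpendicular direction
    perp = np.cross(z, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(z, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    theta = math.radians(angle)
    u = math.cos(theta) * z + math.sin(theta) * perp  # direction h -> A
    # solve |h + r u - s|^2 = distance^2 for r > 0
    b = 2.0 * float(np.dot(u, h - s))
    c = z_len**2 - distance**2
    r = (-b + math.sqrt(b * b - 4.0 * c)) / 2.0
    return h + r * u


def _cys_residue(chain: str, number: int, origin: np.ndarray,
                 sg: np.ndarray, hg: np.ndarray) -> Residue:
    o = np.asarray(origin, float)
    atoms = [
        Atom("N", o + [0.0, 0.0, 0.0], 0, "N"),
        Atom("C", o + [1.46, 0.0, 0.0], 0, "CA"),
        Atom("C", o + [2.2, 1.3, 0.0], 0, "C"),
        Atom("O", o + [3.4, 1.3, 0.0], 0, "O"),
        Atom("C", o + [2.1, -1.2, 0.4], 0, "CB"),
        Atom("S", np.asarray(sg, float), 0, "SG"),
        Atom("H", np.asarray(hg, float), 0, "HG"),
    ]
    return Residue(chain, number, "CYS", atoms)


def _gly_residue(chain: str, number: int, origin: np.ndarray) -> Residue:
    o = np.asarray(origin, float)
    atoms = [
        Atom("N", o + [0.0, 0.0, 0.0], 0, "N"),
        Atom("C", o + [1.46, 0.0, 0.0], 0, "CA"),
        Atom("C", o + [2.2, 1.3, 0.0], 0, "C"),
        Atom("O", o + [3.4, 1.3, 0.0], 0, "O"),
    ]
    return Residue(chain, number, "GLY", atoms)


def gen_pocket_receptor() -> ProteinStructure:
    """A minimal receptor whose CYS 313/314 thiols point into an open pocket.

    The backbone sits on the y = -7 plane; the two thiol S-H groups
    protrude to y ~ 0 so planted ligand acceptors can be positioned freely
    above them without clashing into other residues.
    """
    residues = []
    for number in range(310, 317):
        k = number - 313
        # non-collinear backbone: a rigid fit on the alpha-carbons must pin
        # all three rotational degrees of freedom
        origin = np.array([
            4.5 * k,
            -7.0 + 1.4 * math.sin(2.1 * k),
            2.2 * math.cos(1.7 * k),
        ])
        if number == 313:
            sg = np.array([-2.0, 0.0, 0.0])
            residues.append(_cys_residue("A", number, origin, sg, sg + [0.0, 0.0, 1.34]))
        elif number == 314:
            sg = np.array([2.0, 0.0, 0.0])
            residues.append(_cys_residue("A", number, origin, sg, sg + [0.0, 0.0, 1.34]))
        else:
            residues.append(_gly_residue("A", number, origin))
    return ProteinStructure(residues, source="synthetic pocket")


def _first_carbonyl_oxygen(mol: MolecularGraph) -> int:
    for i, j, order in mol.bonds:
        if order == 2:
            for o_idx, c_idx in ((i, j), (j, i)):
                if mol.atoms[o_idx].element == "O" and mol.atoms[c_idx].element == "C":
                    return o_idx
    raise ValueError("ligand has no carbonyl oxygen")


def _place_acceptor_at(mol: MolecularGraph, acceptor: int, target: np.ndarray,
                       away: np.ndarray) -> MolecularGraph:
    """Rigidly move the ligand so ``acceptor`` lands on ``target`` with the
    rest of the molecule extending along ``away``."""
    coords = mol.coords()
    centroid = coords.mean(axis=0)
    v = centroid - coords[acceptor]
    v_len = np.linalg.norm(v)
    away = np.asarray(away, float)
    away = away / np.linalg.norm(away)
    if v_len > 1e-8:
        # rotate v onto away
        a = v / v_len
        cross = np.cross(a, away)
        dot = float(np.dot(a, away))
        if np.linalg.norm(cross) < 1e-8:
            rot = np.eye(3) if dot > 0 else -np.eye(3) + 2 * np.outer(away, away)
        else:
            k = cross / np.linalg.norm(cross)
            kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            ang = math.acos(np.clip(dot, -1, 1))
            rot = np.eye(3) + math.sin(ang) * kx + (1 - math.cos(ang)) * (kx @ kx)
        coords = (coords - coords[acceptor]) @ rot.T
    else:
        coords = coords - coords[acceptor]
    return mol.with_coords(coords + target)


def gen_receptor_with_pocket(
    n_contact: int = 10,
    n_noncontact: int = 10,
    seed: int = 0,
    ligand: Optional[MolecularGraph] = None,
) -> tuple[ProteinStructure, list[tuple[Pose, bool]]]:
    """Receptor plus poses labelled contact / no-contact by construction.

    Contact poses place a ligand carbonyl oxygen at the planted acceptor
    position of the CYS 314 thiol (2.8 A, 160 deg); no-contact poses are
    displaced far from both cysteines.  ``detect_hbonds`` with the default
    criteria recovers the labels exactly.
    """
    rng = np.random.default_rng(seed)
    protein = gen_pocket_receptor()
    if ligand is None:
        ligand = gen_toy_ligand("isoindoline_dione")
    acc = _first_carbonyl_oxygen(ligand)
    cys = protein.residue("A", 314)
    s, h = cys.atom("SG").coords, cys.atom("HG").coords
    target = _acceptor_position(s, h, CONTACT_DISTANCE, CONTACT_ANGLE)
    base = _place_acceptor_at(ligand, acc, target, away=[0.0, 1.0, 1.0])

    poses: list[tuple[Pose, bool]] = []
    for k in range(n_contact):
        jitter = rng.uniform(-0.1, 0.1, size=3)
        mol = base.with_coords(base.coords() + jitter, id=f"contact{k:03d}")
        poses.append((Pose(mol, program="synthetic"), True))
    for k in range(n_noncontact):
        shift = np.array([0.0, 12.0, 12.0]) + rng.uniform(-1.0, 1.0, size=3)
        mol = base.with_coords(base.coords() + shift, id=f"noncontact{k:03d}")
        poses.append((Pose(mol, program="synthetic"), False))
    return protein, poses


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class PlantedInteraction:
    """One interaction key with a target occupancy or an explicit frame mask."""

    chain: str
    resnum: int
    fraction: Optional[float] = None
    mask: Optional[np.ndarray] = None
    stochastic: bool = False

    def frames_mask(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (n_frames,):
                raise ValueError("mask length must equal n_frames")
            return mask
        if self.fraction is None or not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1] when no mask is given")
        if self.stochastic:
            return rng.random(n_frames) < self.fraction
        k = int(round(self.fraction * n_frames))
        mask = np.zeros(n_frames, dtype=bool)
        mask[:k] = True
        return mask


@dataclass
class TrajectorySpec:
    """Conditions of one planted synthetic trajectory."""

    n_frames: int = 500
    planted: list[PlantedInteraction] = field(default_factory=list)
    sigma: float = 0.05
    seed: int = 0
    frame_interval: float = 200.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def gen_trajectory(
    spec: TrajectorySpec,
    protein: Optional[ProteinStructure] = None,
    ligand: Optional[MolecularGraph] = None,
) -> Trajectory:
    """Trajectory whose planted H-bond keys hold exactly on their planted frames.

    On a planted frame the designated ligand acceptor sits at the 2.8 A /
    160 deg geometry of its residue's thiol donor; elsewhere it sits at
    4.5 A along the same direction (outside the distance cap).  Gaussian
    noise of width ``sigma`` is added to all other atoms; donor and
    acceptor atoms are pinned exactly so detector recovery is exact.
    """
    rng = np.random.default_rng(spec.seed)
    if protein is None:
        protein = gen_pocket_receptor()
    if ligand is None:
        ligand = gen_toy_ligand("isoindoline_dione")

    # assign each planted interaction its own carbonyl/acceptor oxygen
    oxygens = [i for i, a in enumerate(ligand.atoms) if a.element == "O"]
    if len(spec.planted) > len(oxygens):
        raise ValueError("more planted interactions than ligand oxygen acceptors")

    base_lig = _place_acceptor_at(
        ligand,
        oxygens[0] if oxygens else 0,
        np.array([0.0, 4.0, 4.0]),
        away=[0.0, 1.0, 1.0],
    )
    prot_coords = protein.coords()
    lig_coords = base_lig.coords()
    n_prot = len(prot_coords)

    plans = []
    pinned_lig: set[int] = set()
    pinned_prot: set[int] = set()
    for k, planted in enumerate(spec.planted):
        res = protein.residue(planted.chain, planted.resnum)
        s, h = res.atom("SG").coords, res.atom("HG").coords
        near = _acceptor_position(s, h, CONTACT_DISTANCE, CONTACT_ANGLE)
        far = s + (near - s) / np.linalg.norm(near - s) * VIOLATION_DISTANCE
        mask = planted.frames_mask(spec.n_frames, rng)
        acc = oxygens[k]
        plans.append((acc, near, far, mask))
        pinned_lig.add(acc)
        offset = 0
        for r in protein.residues:
            for i, a in enumerate(r.atoms):
                if r is res and a.name in ("SG", "HG"):
                    pinned_prot.add(offset + i)
            offset += len(r.atoms)

    frames = np.empty((spec.n_frames, n_prot + len(lig_coords), 3))
    for f in range(spec.n_frames):
        p = prot_coords + rng.normal(scale=spec.sigma, size=prot_coords.shape)
        l = lig_coords + rng.normal(scale=spec.sigma, size=lig_coords.shape)
        for idx in pinned_prot:
            p[idx] = prot_coords[idx]
        for acc, near, far, mask in plans:
            l[acc] = near if mask[f] else far
        frames[f, :n_prot] = p
        frames[f, n_prot:] = l
    return Trajectory(protein, base_lig, frames, spec.frame_interval)


def gen_two_state_trajectory(
    n_frames: int = 100,
    major_fraction: float = 0.8,
    displacement: float = 4.0,
    sigma: float = 0.05,
    seed: int = 0,
    protein: Optional[ProteinStructure] = None,
    ligand: Optional[MolecularGraph] = None,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory alternating deterministically between two ligand placements.

    Frames cycle so that a ``major_fraction`` share adopt state A and the
    rest state B (ligand displaced by ``displacement``).  Returns the
    trajectory and the boolean per-frame mask of the major state.
    """
    if not (0.5 < major_fraction < 1.0):
        raise ValueError("major_fraction must be in (0.5, 1)")
    rng = np.random.default_rng(seed)
    if protein is None:
        protein = gen_pocket_receptor()
    if ligand is None:
        ligand = gen_toy_ligand("isoindoline_dione")
    base_lig = _place_acceptor_at(
        ligand, _first_carbonyl_oxygen(ligand), np.array([0.0, 4.0, 4.0]),
        away=[0.0, 1.0, 1.0],
    )
    prot_coords = protein.coords()
    lig_a = base_lig.coords()
    lig_b = lig_a + np.array([displacement, 0.0, 0.0])

    period = int(round(1.0 / (1.0 - major_fraction)))
    major_mask = np.array([(f % period) != period - 1 for f in range(n_frames)])

    frames = np.empty((n_frames, len(prot_coords) + len(lig_a), 3))
    for f in range(n_frames):
        p = prot_coords + rng.normal(scale=sigma, size=prot_coords.shape)
        base = lig_a if major_mask[f] else lig_b
        l = base + rng.normal(scale=sigma, size=base.shape)
        frames[f] = np.vstack([p, l])
    return Trajectory(protein, base_lig, frames, 200.0), major_mask
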