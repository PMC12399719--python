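"""Symmetry-aware heavy-atom RMSD between poses of the same ligand.

Docking poses are compared in the receptor frame, so the default RMSD is
in-place (no superposition).  Chemical symmetry (e.g. the two carboxylate
oxygens, phenyl-ring flips) is handled by minimising over the automorphisms
of the heavy-atom multigraph with element labels; bond orders are part of
the edge label, with aromatic treated as its own order.  Hydrogens are
always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._geometry import kabsch_rmsd, rmsd as plain_rmsd
from .chem import MolecularGraph, Pose, PoseEnsemble


@dataclass
class AutomorphismSet:
    """Element- and bond-preserving permutations of a ligand's heavy atoms.

    ``permutations`` are tuples p over heavy-atom positions (0..n_heavy-1,
    in heavy-atom order): heavy atom k maps to heavy atom p[k].
    """

    permutations: list[tuple[int, ...]]

    def __len__(self) -> int:
        return len(self.permutations)


def heavy_atom_graph(graph: MolecularGraph) -> nx.Graph:
    """Heavy-atom graph with element node labels and bond-order edge labels."""
    heavy = graph.heavy_indices
    pos = {atom_idx: k for k, atom_idx in enumerate(heavy)}
    g = nx.Graph()
    for atom_idx, k in pos.items():
        g.add_node(k, element=graph.atoms[atom_idx].element)
    for i, j, order in graph.bonds:
        if i in pos and j in pos:
            g.add_edge(pos[i], pos[j], order=order)
    return g


def find_automorphisms(graph: MolecularGraph, max_count: int = 10000) -> AutomorphismSet:
    """All label-preserving heavy-atom permutations, via VF2 backtracking."""
    g = heavy_atom_graph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("molecule has no heavy atoms")
    if not nx.is_connected(g):
        raise ValueError("heavy-atom graph must be connected")
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    perms: list[tuple[int, ...]] = []
    n = g.number_of_nodes()
    for mapping in matcher.isomorphisms_iter():
        perms.append(tuple(mapping[k] for k in range(n)))
        if len(perms) > max_count:
            raise ValueError(
                f"more than {max_count} automorphisms; raise max_count to proceed"
            )
    perms.sort()
    return AutomorphismSet(perms)


def _isomorphisms_between(a: MolecularGraph, b: MolecularGraph) -> list[tuple[int, ...]]:
    ga, gb = heavy_atom_graph(a), heavy_atom_graph(b)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        ga,
        gb,
        node_match=lambda x, y: x["element"] == y["element"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    n = ga.number_of_nodes()
    return [tuple(m[k] for k in range(n)) for m in matcher.isomorphisms_iter()]


def pose_rmsd(
    pose_a: Pose | MolecularGraph,
    pose_b: Pose | MolecularGraph,
    symmetry: bool = True,
    superpose: bool = False,
) -> float:
    """Heavy-atom RMSD between two conformations of the same ligand.

    With ``symmetry`` the minimum over all graph automorphisms is returned;
    with ``superpose`` an optimal Kabsch fit is applied per automorphism
    before the deviation is measured.
    """
    ga = pose_a.ligand if isinstance(pose_a, Pose) else pose_a
    gb = pose_b.ligand if isinstance(pose_b, Pose) else pose_b
    xa, xb = ga.heavy_coords(), gb.heavy_coords()
    if xa.shape != xb.shape:
        raise ValueError("poses have different heavy-atom counts")
    metric = kabsch_rmsd if superpose else plain_rmsd
    if not symmetry:
        ea = [ga.atoms[i].element for i in ga.heavy_indices]
        eb = [gb.atoms[i].element for i in gb.heavy_indices]
        if ea != eb:
            raise ValueError("heavy-atom element sequences differ; cannot pair by index")
        return metric(xa, xb)
    mappings = _isomorphisms_between(ga, gb)
    if not mappings:
        raise ValueError("ligand graphs are not isomorphic as labeled multigraphs")
    best = np.inf
    for p in mappings:
        # heavy atom k of A pairs with heavy atom p[k] of B
        val = metric(xa, xb[np.asarray(p)])
        if val < best:
            best = val
    return float(best)


@dataclass
class RmsdMatrix:
    """Symmetric pose-vs-pose RMSD matrix with program-name labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("matrix must be square")
        if len(self.labels) != n:
            raise ValueError("labels must match matrix size")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def rmsd_matrix(ensemble: PoseEnsemble, symmetry: bool = True,
                superpose: bool = False) -> RmsdMatrix:
    """Full symmetric pairwise pose-RMSD matrix for one ligand's ensemble.

    All poses share one ligand graph, so the automorphism set is enumerated
    once and reused for every pair.
    """
    poses = ensemble.poses
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    coords = [p.ligand.heavy_coords() for p in poses]
    shape0 = coords[0].shape
    for c in coords[1:]:
        if c.shape != shape0:
            raise ValueError("poses have different heavy-atom counts")
    if symmetry:
        perms = [np.asarray(p) for p in find_automorphisms(poses[0].ligand).permutations]
    else:
        perms = [np.arange(shape0[0])]
    metric = kabsch_rmsd if superpose else plain_rmsd
    n = len(poses)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            best = min(metric(coords[i], coords[j][p]) for p in perms)
            values[i, j] = values[j, i] = best
    return RmsdMatrix(values, [p.program for p in poses])


def redock_pass(predicted: Pose, reference: Pose, threshold: float = 3.0) -> bool:
    """Redocking acceptance: symmetry-aware RMSD to the reference <= threshold.

    The boundary is inclusive; 3.0 A is the conventional acceptance cap for
    reproducing a crystallographic ligand placement.
    """
    return pose_rmsd(predicted, reference) <= threshold
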