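"""Pose-consensus clustering and selection.

The multi-program pose ensemble of one ligand is clustered by agglomerative
complete linkage on the pairwise symmetry-corrected RMSD matrix.  Merging
stops when the smallest complete-linkage (maximum pairwise) distance between
clusters exceeds the cutoff (default 2.0 A, inclusive), which guarantees
that every within-cluster pose pair is within the cutoff.  The consensus
level is the number of distinct docking programs represented in the largest
cluster; ligands reaching a minimum level (default 9 of 12) are selected.

All tie-breaking is deterministic (smallest pose index); there is no
randomness anywhere in this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .rmsd import RmsdMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """A partition of pose indices with its guaranteeing cutoff."""

    assignments: list[int]  # pose index -> cluster id
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments))

    @property
    def clusters(self) -> list[list[int]]:
        """Members per cluster id, each member list ascending."""
        out: dict[int, list[int]] = {}
        for pose, cid in enumerate(self.assignments):
            out.setdefault(cid, []).append(pose)
        return [out[c] for c in sorted(out)]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def _as_matrix(matrix: Union[RmsdMatrix, np.ndarray]) -> np.ndarray:
    values = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, float)
    n = values.shape[0]
    if values.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.any(values < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    return values


def complete_linkage(matrix: Union[RmsdMatrix, np.ndarray], cutoff: float = 2.0) -> ClusterResult:
    """Agglomerative complete-linkage clustering cut at ``cutoff`` (inclusive).

    Clusters are merged greedily by smallest complete-linkage distance;
    ties are broken by the pair containing the smallest pose index.  The
    result is therefore deterministic and invariant to pose reordering.
    """
    values = _as_matrix(matrix)
    n = values.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]

    def linkdist(a: list[int], b: list[int]) -> float:
        return max(values[i, j] for i in a for j in b)

    while len(clusters) > 1:
        best = None  # (distance, min_member, other_member, idx_a, idx_b)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                d = linkdist(clusters[ia], clusters[ib])
                key = (d, min(clusters[ia][0], clusters[ib][0]),
                       max(clusters[ia][0], clusters[ib][0]))
                if best is None or key < best[0]:
                    best = (key, ia, ib)
        (d, _, _), ia, ib = best
        if d > cutoff:
            break
        merged = sorted(clusters[ia] + clusters[ib])
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])

    assignments = [0] * n
    # stable cluster ids: descending size, then smallest member
    ordered = sorted(clusters, key=lambda c: (-len(c), c[0]))
    for cid, members in enumerate(ordered):
        for m in members:
            assignments[m] = cid
    return ClusterResult(assignments, cutoff)


@dataclass
class ConsensusScore:
    """Distinct-program count and raw size of the largest pose cluster."""

    level: int
    largest_cluster_size: int

    def __post_init__(self) -> None:
        if not (1 <= self.level <= self.largest_cluster_size):
            raise ValueError("need 1 <= level <= largest cluster size")


def consensus_level(result: ClusterResult, programs: Sequence[str]) -> ConsensusScore:
    """Consensus level of an ensemble from its cluster partition.

    The largest cluster is chosen by size; size ties go to the cluster with
    more distinct programs, then to the one containing the smallest pose
    index.  Duplicate poses from one program count once for the level.
    """
    if len(programs) != len(result.assignments):
        raise ValueError("program labels must align with the clustered poses")
    best = None
    for members in result.clusters:
        distinct = len({programs[m] for m in members})
        key = (len(members), distinct, -members[0])
        if best is None or key > best[0]:
            best = (key, members, distinct)
    _, members, distinct = best
    return ConsensusScore(level=distinct, largest_cluster_size=len(members))


def select_by_consensus(
    scores: Mapping[str, Union[ConsensusScore, int]],
    min_level: int = 9,
) -> tuple[list[str], dict[int, int]]:
    """Ligands whose consensus level reaches ``min_level``, plus a level histogram."""
    if min_level < 1:
        raise ValueError("min_level must be >= 1")
    levels = {
        lig: (s.level if isinstance(s, ConsensusScore) else int(s))
        for lig, s in scores.items()
    }
    histogram: dict[int, int] = {}
    for lv in levels.values():
        histogram[lv] = histogram.get(lv, 0) + 1
    if levels and min_level > max(levels.values()):
        warnings.warn(
            f"min_level {min_level} exceeds the highest observed consensus "
            f"level {max(levels.values())}; selection is empty",
            stacklevel=2,
        )
    selected = sorted(lig for lig, lv in levels.items() if lv >= min_level)
    return selected, dict(sorted(histogram.items(), reverse=True))


def delta_g_combine(e_complex: float, e_ligand: float, e_receptor: float) -> float:
    """Binding free energy from component energies: E_complex - E_ligand - E_receptor.

    Component energies (kcal/mol) are supplied externally, e.g. from an
    MM-GBSA rescoring engine; only the combination arithmetic lives here.
    """
    for v in (e_complex, e_ligand, e_receptor):
        if not np.isfinite(v):
            raise ValueError("component energies must be finite")
    return float(e_complex - e_ligand - e_receptor)
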