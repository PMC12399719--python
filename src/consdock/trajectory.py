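"""MD-trajectory analyses: RMSD time series, interaction occupancy,
stride-based clustering with representative-frame extraction.

Every frame is first superposed onto the reference frame (frame 0 by
default) by a Kabsch fit on the protein alpha-carbons; protein RMSD is then
measured over the alpha-carbons and ligand RMSD over the ligand heavy atoms
in that fitted frame.  Occupancy is the fraction of analysed frames in
which a given interaction key (kind + protein residue) is detected at least
once.  Trajectory clustering subsamples every stride-th frame, builds the
pairwise ligand-heavy-atom RMSD matrix and reuses the consensus module's
complete-linkage clustering; the representative is the member of the most
populated cluster minimising its summed RMSD to co-members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geometry import kabsch, rmsd as plain_rmsd
from .chem import Pose, Trajectory
from .consensus import ClusterResult, complete_linkage
from .interactions import (
    HBondCriteria,
    detect_halogen,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi_stack,
)

_SELECTIONS = ("protein_alpha_carbons", "ligand_heavy_atoms")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (A) of one selection versus the reference frame."""

    selection: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _fitted_frames(traj: Trajectory, reference: Optional[np.ndarray] = None) -> np.ndarray:
    """All frames superposed onto the reference by an alpha-carbon Kabsch fit."""
    ca = traj.ca_indices()
    if ca.size == 0:
        raise ValueError("no alpha-carbon (CA) atoms in topology")
    ref = traj.frames[0] if reference is None else np.asarray(reference, float)
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        r, t = kabsch(traj.frames[f][ca], ref[ca])
        out[f] = traj.frames[f] @ r.T + t
    return out


def rmsd_series(
    traj: Trajectory,
    selection: str,
    reference: Optional[np.ndarray] = None,
) -> RmsdSeries:
    """RMSD time series vs the reference frame (frame 0 unless given)."""
    if selection not in _SELECTIONS:
        raise ValueError(f"selection must be one of {_SELECTIONS}")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = traj.ca_indices() if selection == "protein_alpha_carbons" \
        else traj.ligand_heavy_indices()
    ref = traj.frames[0] if reference is None else np.asarray(reference, float)
    fitted = _fitted_frames(traj, ref)
    values = [plain_rmsd(fitted[f][idx], ref[idx]) for f in range(traj.n_frames)]
    return RmsdSeries(selection, np.array(values))


@dataclass
class OccupancyReport:
    """Interaction-key -> fraction of analysed frames; zero keys omitted."""

    fractions: dict[tuple, float]
    n_frames: int

    def __post_init__(self) -> None:
        for k, v in self.fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"occupancy fraction out of [0, 1] for {k}")
        self.fractions = {k: v for k, v in self.fractions.items() if v > 0.0}


_DETECTORS = {
    "hbond": lambda pose, prot, scope, kw: detect_hbonds(
        pose, prot, kw.get("criteria", HBondCriteria()), residue_filter=scope),
    "pi_stack": lambda pose, prot, scope, kw: detect_pi_stack(
        pose, prot, kw.get("pi_d_max", 5.5), kw.get("pi_angle_tol", 30.0),
        residue_filter=scope),
    "hydrophobic": lambda pose, prot, scope, kw: detect_hydrophobic(
        pose, prot, kw.get("hydrophobic_d_max", 4.5), residue_filter=scope),
    "halogen": lambda pose, prot, scope, kw: detect_halogen(
        pose, prot, kw.get("halogen_d_max", 3.6), kw.get("halogen_angle_min", 140.0),
        residue_filter=scope),
}


def occupancy(
    traj: Trajectory,
    kinds: Sequence[str] = ("hbond",),
    residue_filter: Optional[Sequence[tuple[str, int]]] = None,
    **detector_kwargs,
) -> OccupancyReport:
    """Per-interaction-key occupancy fractions over all frames.

    A frame counts once per key (kind, chain, residue number) even when
    several atom pairs qualify in that frame.
    """
    unknown = set(kinds) - set(_DETECTORS)
    if unknown:
        raise ValueError(f"unknown detector kinds: {sorted(unknown)}")
    if traj.ligand is None:
        raise ValueError("trajectory carries no ligand")
    counts: dict[tuple, int] = {}
    for f in range(traj.n_frames):
        prot = traj.protein_at(f)
        pose = Pose(traj.ligand_at(f), program="frame")
        seen: set[tuple] = set()
        for kind in kinds:
            for rec in _DETECTORS[kind](pose, prot, residue_filter, detector_kwargs):
                seen.add(rec.occupancy_key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    fractions = {k: c / traj.n_frames for k, c in counts.items()}
    return OccupancyReport(fractions, traj.n_frames)


@dataclass
class TrajectoryClusters:
    """Clustering of the subsampled frames, plus the representative frame."""

    frame_indices: np.ndarray       # original frame index of each subsampled frame
    assignments: np.ndarray         # cluster id per subsampled frame; -1 = unclustered
    representative: int             # original frame index
    matrix: np.ndarray              # pairwise ligand RMSD between subsampled frames
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(int(a) for a in self.assignments if a >= 0))

    def members(self, cluster_id: int) -> np.ndarray:
        return self.frame_indices[self.assignments == cluster_id]


def cluster_trajectory(
    traj: Trajectory,
    cutoff: float,
    stride: int = 10,
    max_clusters: int = 5,
) -> TrajectoryClusters:
    """Stride-subsampled complete-linkage clustering on ligand-pose RMSD.

    The stride is in frames.  When the partition exceeds ``max_clusters``,
    only the largest ``max_clusters`` clusters are kept and the remaining
    frames are pooled as unclustered (id -1).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = traj.subsample(stride)
    if sub.n_frames < 2:
        raise ValueError("fewer than 2 frames after subsampling")
    frame_indices = np.arange(traj.n_frames)[::stride]

    fitted = _fitted_frames(sub)
    lig = sub.ligand_heavy_indices()
    n = sub.n_frames
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = plain_rmsd(fitted[i][lig], fitted[j][lig])

    result: ClusterResult = complete_linkage(matrix, cutoff)
    assignments = np.asarray(result.assignments, dtype=int)
    # cluster ids from complete_linkage are already ordered by descending size
    if result.n_clusters > max_clusters:
        assignments = np.where(assignments < max_clusters, assignments, -1)

    members0 = np.flatnonzero(assignments == 0)
    sums = matrix[np.ix_(members0, members0)].sum(axis=1)
    rep_sub = int(members0[int(np.argmin(sums))])
    return TrajectoryClusters(
        frame_indices, assignments, int(frame_indices[rep_sub]), matrix, cutoff
    )


def split_report(
    traj: Trajectory,
    windows: Sequence[tuple[int, int]],
    metric: str = "occupancy",
    **kwargs,
):
    """Recompute a metric independently per frame window.

    Windows are half-open frame ranges ``(start, stop)``; each window is
    treated as a trajectory in its own right (its first frame is the RMSD
    reference).  Empty or out-of-range windows raise.
    """
    reports = []
    for start, stop in windows:
        if not (0 <= start < stop <= traj.n_frames):
            raise ValueError(f"invalid window ({start}, {stop}) for {traj.n_frames} frames")
        sub = Trajectory(traj.protein, traj.ligand, traj.frames[start:stop],
                         traj.frame_interval)
        if metric == "occupancy":
            reports.append(occupancy(sub, **kwargs))
        elif metric == "rmsd_series":
            reports.append(rmsd_series(sub, **kwargs))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return reports
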