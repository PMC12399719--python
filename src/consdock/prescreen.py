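"""Stage-1 library filters: substructure, shape similarity, drug-likeness.

Shape model
-----------
Each heavy atom carries an isotropic Gaussian density

    rho_i(r) = P * exp(-alpha * |r - c_i|^2)

with one uniform radius R (default 1.70 A).  Amplitude and width are fixed
by requiring that, for an isolated atom, both the integral of the density
and the self-overlap integral equal the hard-sphere volume
V_s = (4/3) * pi * R^3.  That pins P = 2*sqrt(2) and
alpha = 2*pi / V_s^(2/3), and makes the single-atom self-overlap exactly
one hard sphere.  The molecular overlap volume is the first-order
(pairwise) integral of the two density sums, which for a product of sums
is analytic and exact:

    V_AB = V_s * sum_ij exp(-alpha * d_ij^2 / 2)

The shape Tanimoto is V_AB / (V_AA + V_BB - V_AB), in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .chem import MolecularGraph
from .reports import StageReport

DEFAULT_RADIUS = 1.70

_AMPLITUDE = 2.0 * math.sqrt(2.0)


def _sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


def _alpha(radius: float) -> float:
    return 2.0 * math.pi / _sphere_volume(radius) ** (2.0 / 3.0)


def gaussian_density(coords: np.ndarray, points: np.ndarray,
                     radius: float = DEFAULT_RADIUS) -> np.ndarray:
    """Summed atomic Gaussian density evaluated at arbitrary points.

    Exposed so that an independent grid integration can consume the exact
    same density the analytic overlap assumes.
    """
    a = _alpha(radius)
    out = np.zeros(len(points))
    for c in np.atleast_2d(coords):
        d2 = np.sum((points - c) ** 2, axis=1)
        out += _AMPLITUDE * np.exp(-a * d2)
    return out


def _heavy(mol: Union[MolecularGraph, np.ndarray]) -> np.ndarray:
    if isinstance(mol, MolecularGraph):
        coords = mol.heavy_coords()
    else:
        coords = np.atleast_2d(np.asarray(mol, dtype=float))
    if coords.size == 0:
        raise ValueError("molecule has no heavy atoms")
    return coords


def gaussian_overlap_volume(mol_a, mol_b, radius: float = DEFAULT_RADIUS) -> float:
    """Analytic first-order Gaussian overlap volume, in A^3 (symmetric, >= 0)."""
    xa, xb = _heavy(mol_a), _heavy(mol_b)
    a = _alpha(radius)
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=2)
    return float(_sphere_volume(radius) * np.sum(np.exp(-a * d2 / 2.0)))


@dataclass
class ShapeOverlapResult:
    overlap_ab: float
    self_a: float
    self_b: float

    @property
    def tanimoto(self) -> float:
        t = self.overlap_ab / (self.self_a + self.self_b - self.overlap_ab)
        return float(min(max(t, 0.0), 1.0))


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Center coordinates and rotate into the principal-axes frame."""
    x = coords - coords.mean(axis=0)
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    v = v[:, np.argsort(w)[::-1]]  # descending variance
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return x @ v


_PROPER_FLIPS = (
    np.diag([1.0, 1.0, 1.0]),
    np.diag([1.0, -1.0, -1.0]),
    np.diag([-1.0, 1.0, -1.0]),
    np.diag([-1.0, -1.0, 1.0]),
)


def shape_tanimoto(mol_a, mol_b, align: str = "none",
                   radius: float = DEFAULT_RADIUS) -> ShapeOverlapResult:
    """Gaussian shape-overlap Tanimoto between two molecules.

    ``align='principal_axes'`` centres both molecules, rotates each into its
    own principal-axes frame, tries the 4 proper axis flips of B and keeps
    the orientation maximising the Tanimoto.  No gradient refinement is done.
    """
    if align not in ("none", "principal_axes"):
        raise ValueError(f"unknown align mode {align!r}")
    xa, xb = _heavy(mol_a), _heavy(mol_b)
    self_a = gaussian_overlap_volume(xa, xa, radius)
    self_b = gaussian_overlap_volume(xb, xb, radius)
    if align == "none":
        return ShapeOverlapResult(gaussian_overlap_volume(xa, xb, radius), self_a, self_b)
    pa, pb = _principal_frame(xa), _principal_frame(xb)
    best = -np.inf
    for flip in _PROPER_FLIPS:
        ov = gaussian_overlap_volume(pa, pb @ flip, radius)
        best = max(best, ov)
    return ShapeOverlapResult(best, self_a, self_b)


def filter_by_shape(
    library: Sequence[MolecularGraph],
    query: MolecularGraph,
    threshold: float = 0.65,
    align: str = "principal_axes",
    radius: float = DEFAULT_RADIUS,
    n_initial: Optional[int] = None,
) -> tuple[list[str], StageReport, dict[str, float]]:
    """Keep library members whose shape Tanimoto to the query is >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    scores = {m.id: shape_tanimoto(m, query, align=align, radius=radius).tanimoto
              for m in library}
    survivors = [m.id for m in library if scores[m.id] >= threshold]
    report = StageReport("shape", len(library), len(survivors),
                         n_initial or max(len(library), 1))
    return survivors, report, scores


# ---------------------------------------------------------------------------
# Rule-based drug-likeness


@dataclass
class DruglikeRule:
    descriptor: str
    min: float = -math.inf
    max: float = math.inf

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError("rule min must be <= max")

    def ok(self, value: float) -> bool:
        return self.min <= value <= self.max


#: Lipinski Rule of Five.
RO5_RULES = [
    DruglikeRule("MW", max=500.0),
    DruglikeRule("logP", max=5.0),
    DruglikeRule("donors", max=5.0),
    DruglikeRule("acceptors", max=10.0),
]

#: RO5 plus conventional property windows for solubility and polar surface.
DEFAULT_ADME_RULES = RO5_RULES + [
    DruglikeRule("logS", min=-6.5, max=0.5),
    DruglikeRule("PSA", min=7.0, max=200.0),
]


def druglike_check(
    table: pd.DataFrame,
    rules: Sequence[DruglikeRule] = RO5_RULES,
) -> pd.DataFrame:
    """Per-compound pass/fail against descriptor range rules.

    ``table`` is indexed by compound id with one named real column per
    descriptor (descriptors are computed elsewhere or user-supplied).
    Returns the table augmented with ``passed`` and ``violations`` columns.
    """
    table = pd.DataFrame(table)
    for rule in rules:
        if rule.descriptor not in table.columns:
            missing = ", ".join(map(str, table.index[:3]))
            raise KeyError(
                f"descriptor {rule.descriptor!r} missing for compounds [{missing}...]"
            )
    passed, violations = [], []
    for _, row in table.iterrows():
        bad = [r.descriptor for r in rules if not r.ok(float(row[r.descriptor]))]
        violations.append(",".join(bad))
        passed.append(not bad)
    out = table.copy()
    out["passed"] = passed
    out["violations"] = violations
    return out


def compute_descriptors(graphs: Sequence[MolecularGraph]) -> pd.DataFrame:
    """RO5 descriptors (MW, logP, donors, acceptors) computed with RDKit."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    from .io import to_rdkit

    rows = {}
    for g in graphs:
        mol = to_rdkit(g, with_coords=False)
        Chem.SanitizeMol(mol)
        rows[g.id] = {
            "MW": Descriptors.MolWt(mol),
            "logP": Crippen.MolLogP(mol),
            "donors": Lipinski.NumHDonors(mol),
            "acceptors": Lipinski.NumHAcceptors(mol),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
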