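"""Independent brute-force / numeric oracles used by the test suite.

Everything here is deliberately written from first principles, without
calling the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# graph automorphisms by exhaustive permutation enumeration


def brute_force_automorphisms(elements, bonds):
    """All element- and bond-preserving permutations of a labelled graph.

    ``elements``: list of element symbols (heavy atoms only).
    ``bonds``: list of (i, j, order).
    Permutations are enumerated within element classes only (a permutation
    across elements can never preserve labels), which keeps <= 9-atom graphs
    tractable while remaining exhaustive.
    """
    n = len(elements)
    bond_multiset = {}
    for i, j, order in bonds:
        key = (min(i, j), max(i, j), order)
        bond_multiset[key] = bond_multiset.get(key, 0) + 1

    classes: dict[str, list[int]] = {}
    for idx, el in enumerate(elements):
        classes.setdefault(el, []).append(idx)

    class_lists = list(classes.values())
    perms = []
    for combo in itertools.product(*[itertools.permutations(c) for c in class_lists]):
        perm = [0] * n
        for orig, mapped in zip(class_lists, combo):
            for src, dst in zip(orig, mapped):
                perm[src] = dst
        mapped_bonds = {}
        for (i, j, order), count in bond_multiset.items():
            a, b = perm[i], perm[j]
            key = (min(a, b), max(a, b), order)
            mapped_bonds[key] = mapped_bonds.get(key, 0) + count
        if mapped_bonds == bond_multiset:
            perms.append(tuple(perm))
    return sorted(perms)


def brute_force_min_rmsd(coords_a, coords_b, permutations):
    """Minimum in-place RMSD over an explicit permutation list."""
    best = math.inf
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    for p in permutations:
        d = a - b[list(p)]
        best = min(best, math.sqrt(float(np.mean(np.sum(d * d, axis=1)))))
    return best


# ---------------------------------------------------------------------------
# Gaussian overlap by direct grid integration


def grid_overlap_volume(coords_a, coords_b, radius=1.70, spacing=0.05, padding=4.5):
    """Numeric integral of the product of two summed-Gaussian densities.

    The density model is re-derived here from its defining constraints:
    amplitude P and width alpha such that the integral of a single atomic
    Gaussian and its self-overlap both equal the hard-sphere volume.
    """
    vs = 4.0 / 3.0 * math.pi * radius**3
    amplitude = 2.0 * math.sqrt(2.0)
    alpha = 2.0 * math.pi / vs ** (2.0 / 3.0)

    coords_a = np.atleast_2d(np.asarray(coords_a, float))
    coords_b = np.atleast_2d(np.asarray(coords_b, float))
    allc = np.vstack([coords_a, coords_b])
    lo = allc.min(axis=0) - padding
    hi = allc.max(axis=0) + padding
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    xs, ys, zs = axes
    xv, yv = np.meshgrid(xs, ys, indexing="ij")
    total = 0.0
    for z in zs:  # chunk over z to bound memory
        rho_a = np.zeros_like(xv)
        for c in coords_a:
            d2 = (xv - c[0]) ** 2 + (yv - c[1]) ** 2 + (z - c[2]) ** 2
            rho_a += amplitude * np.exp(-alpha * d2)
        rho_b = np.zeros_like(xv)
        for c in coords_b:
            d2 = (xv - c[0]) ** 2 + (yv - c[1]) ** 2 + (z - c[2]) ** 2
            rho_b += amplitude * np.exp(-alpha * d2)
        total += float(np.sum(rho_a * rho_b))
    return total * spacing**3


# ---------------------------------------------------------------------------
# set partitions (for complete-linkage validity)


def set_partitions(items):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def valid_partition(blocks, matrix, cutoff):
    """Every block's max pairwise distance is within the cutoff."""
    for block in blocks:
        for i in block:
            for j in block:
                if matrix[i][j] > cutoff:
                    return False
    return True


# ---------------------------------------------------------------------------
# double-loop interaction oracles


def double_loop_hbonds(lig_atoms, lig_bonds, protein_residues, d_max=3.5, angle_min=120.0):
    """Exhaustive H-bond enumeration over every donor-H/acceptor pair.

    ``lig_atoms``: list of (element, xyz); ``lig_bonds``: (i, j) pairs.
    ``protein_residues``: list of (chain, resnum, resname,
    [(name, element, xyz), ...]).  Returns a set of hashable descriptors.
    """

    def ang(a, v, b):
        u1 = np.asarray(a, float) - np.asarray(v, float)
        u2 = np.asarray(b, float) - np.asarray(v, float)
        c = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    adj: dict[int, list[int]] = {}
    for i, j in lig_bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    found = set()
    polar = {"N", "O", "S"}
    for chain, resnum, resname, atoms in protein_residues:
        # ligand donor -> protein acceptor
        for d, (el_d, xd) in enumerate(lig_atoms):
            if el_d not in polar:
                continue
            for h in adj.get(d, []):
                if lig_atoms[h][0] != "H":
                    continue
                xh = lig_atoms[h][1]
                for name_a, el_a, xa in atoms:
                    if el_a not in polar:
                        continue
                    dist = float(np.linalg.norm(np.asarray(xd) - np.asarray(xa)))
                    if dist <= d_max and ang(xd, xh, xa) > angle_min:
                        found.add(("lig_donor", d, h, chain, resnum, name_a))
        # protein donor -> ligand acceptor
        for di, (name_d, el_d, xd) in enumerate(atoms):
            if el_d not in polar:
                continue
            for name_h, el_h, xh in atoms:
                if el_h != "H":
                    continue
                if np.linalg.norm(np.asarray(xh) - np.asarray(xd)) > 1.35:
                    continue
                for a, (el_a, xa) in enumerate(lig_atoms):
                    if el_a not in polar:
                        continue
                    dist = float(np.linalg.norm(np.asarray(xd) - np.asarray(xa)))
                    if dist <= d_max and ang(xd, xh, xa) > angle_min:
                        found.add(("prot_donor", a, chain, resnum, name_d))
    return found


def double_loop_halogen(lig_atoms, lig_bonds, protein_residues, d_max=3.6, angle_min=140.0):
    """Exhaustive C-X...acceptor enumeration (X in Cl/Br/I)."""

    def ang(a, v, b):
        u1 = np.asarray(a, float) - np.asarray(v, float)
        u2 = np.asarray(b, float) - np.asarray(v, float)
        c = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    adj: dict[int, list[int]] = {}
    for i, j in lig_bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    found = set()
    for chain, resnum, resname, atoms in protein_residues:
        for x, (el_x, xx) in enumerate(lig_atoms):
            if el_x not in ("Cl", "Br", "I"):
                continue
            carbons = [j for j in adj.get(x, []) if lig_atoms[j][0] == "C"]
            if not carbons:
                continue
            xc = lig_atoms[carbons[0]][1]
            for name_a, el_a, xa in atoms:
                if el_a not in ("N", "O", "S"):
                    continue
                dist = float(np.linalg.norm(np.asarray(xx) - np.asarray(xa)))
                if dist <= d_max and ang(xc, xx, xa) >= angle_min:
                    found.add((x, chain, resnum, name_a))
    return found


def double_loop_hydrophobic(lig_atoms, protein_residues, apolar, d_max=4.5):
    """Residues with at least one ligand-C / side-chain-C contact."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    found = set()
    for chain, resnum, resname, atoms in protein_residues:
        if resname not in apolar:
            continue
        for name_a, el_a, xa in atoms:
            if el_a != "C" or name_a in backbone:
                continue
            for el_l, xl in lig_atoms:
                if el_l != "C":
                    continue
                if np.linalg.norm(np.asarray(xl) - np.asarray(xa)) <= d_max:
                    found.add((chain, resnum))
    return found
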