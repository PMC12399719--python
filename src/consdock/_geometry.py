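"""Small geometric primitives: Kabsch superposition, angles, rigid transforms."""

from __future__ import annotations

import numpy as np


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain in-place RMSD between two (n, 3) coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have the same shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |mobile @ R.T + t - reference|.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` superposes onto
    ``reference`` in the least-squares sense (proper rotation only).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    p, q = mobile - cm, reference - cr
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = cr - r @ cm
    return r, t


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of a onto b."""
    r, t = kabsch(a, b)
    return rmsd(a @ r.T + t, b)


def superpose(mobile_fit: np.ndarray, reference_fit: np.ndarray,
              mobile_all: np.ndarray) -> np.ndarray:
    """Fit on one selection, apply the transform to the full coordinate set."""
    r, t = kabsch(mobile_fit, reference_fit)
    return mobile_all @ r.T + t


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees."""
    u = np.asarray(a, dtype=float) - vertex
    v = np.asarray(b, dtype=float) - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
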