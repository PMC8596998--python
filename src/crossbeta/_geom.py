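"""Small vector-geometry kernel shared by the builder and trajectory metrics.

Everything operates on plain ``(N, 3)`` float arrays in Angstrom.  Dihedral
signs follow the IUPAC convention (cis = 0, trans = +/-180).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "unit", "angle_deg", "dihedral_deg", "nerf_place", "kabsch",
    "superpose", "lsq_plane",
]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def angle_deg(a, b, c) -> float:
    """Interior angle a-b-c in degrees."""
    u = unit(np.asarray(a, float) - b)
    v = unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = unit(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    Returns the position of d such that dist(c, d) = bond, the interior angle
    b-c-d equals ``angle`` (degrees) and the IUPAC torsion a-b-c-d equals
    ``torsion`` (degrees).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tors = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tors),
        bond * np.sin(ang) * np.sin(tors),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with the least-squares rigid transform
    ``x -> R @ x + t`` (proper rotation, det(R) = +1).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects two congruent (N, 3) arrays")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``target``."""
    R, t = kabsch(mobile, target)
    return mobile @ R.T + t


def lsq_plane(points: np.ndarray):
    """Least-squares plane through points; returns (centroid, unit normal)."""
    P = np.asarray(points, float)
    c = P.mean(axis=0)
    _, _, Vt = np.linalg.svd(P - c)
    return c, Vt[2]
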