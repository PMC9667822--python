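"""Vector primitives shared by all analysis modules.

All angles at API boundaries are in degrees; all lengths in angstroms.
Points are numpy arrays of shape (3,) (any array-like is accepted).
"""

from __future__ import annotations

import numpy as np

__all__ = ["distance", "angle", "dihedral", "DihedralUndefined", "best_fit_plane", "rotation_matrix"]


class DihedralUndefined(ValueError):
    """Raised when a dihedral is degenerate (three consecutive points collinear)."""


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected 3-vector, got shape {v.shape}")
    return v


def distance(a, b) -> float:
    """Euclidean distance between two points."""
    return float(np.linalg.norm(_as_vec(a) - _as_vec(b)))


def angle(a, vertex, c) -> float:
    """Interior angle at *vertex*, in degrees in [0, 180]."""
    u = _as_vec(a) - _as_vec(vertex)
    v = _as_vec(c) - _as_vec(vertex)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length arm in angle()")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Sign follows the IUPAC convention: looking from p2 toward p3, the
    angle is positive when the far bond (p3->p4) is rotated clockwise
    relative to the near bond (p2->p1 projected).
    """
    p1, p2, p3, p4 = (_as_vec(p) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DihedralUndefined("collinear points make the torsion undefined")
    m1 = np.cross(n1, b2 / nb2)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through *points* (n, 3).

    Returns (centroid, unit normal). The normal is the singular vector
    with the smallest singular value; its overall sign is fixed so the
    first nonzero component is positive (determinism).
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    for comp in normal:
        if abs(comp) > 1e-12:
            if comp < 0:
                normal = -normal
            break
    return centroid, normal


def rotation_matrix(axis, theta_deg: float) -> np.ndarray:
    """Rotation matrix about *axis* by *theta_deg* (right-handed)."""
    ax = _as_vec(axis)
    n = np.linalg.norm(ax)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = ax / n
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )
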