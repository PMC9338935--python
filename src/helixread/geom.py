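"""Low-level vector geometry shared by all analysis modules.

Angles are in degrees everywhere in the public API and wrapped to
(-180, +180]; rotation matrices are right-handed and act on column
vectors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "angle_between",
    "dihedral",
    "rotation_about_axis",
    "superpose",
    "fibonacci_sphere",
]


def wrap_angle(deg):
    """Wrap an angle (or array of angles) in degrees to (-180, +180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # map -180 -> +180 to keep the half-open convention
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(deg) or np.ndim(deg) == 0 else wrapped


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Looking from p2 to p3, the angle is positive when the far bond
    (p3->p4) is rotated clockwise relative to the near bond (p2->p1
    projected), i.e. the standard atan2 formulation.
    """
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(-np.degrees(np.arctan2(y, x)))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis has zero length")
    x, y, z = axis / n
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def superpose(mobile: np.ndarray, target: np.ndarray, weights=None):
    """Least-squares rigid superposition (Kabsch, via SVD).

    Finds rotation ``R`` and translation ``t`` minimising
    ``sum w_i |R @ mobile_i + t - target_i|^2``.

    Returns
    -------
    R : (3, 3) proper rotation matrix
    t : (3,) translation
    rmsd : weighted root-mean-square deviation after superposition
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects matching (n, 3) arrays")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    A = mobile - mc
    B = target - tc
    H = (w[:, None] * A).T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    diff = (R @ mobile.T).T + t - target
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return R, t, rmsd


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    golden = (1.0 + 5.0 ** 0.5) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
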