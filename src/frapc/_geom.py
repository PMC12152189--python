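"""Shared low-level vector geometry.

Degrees everywhere at the interface; radians never leave a function.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError

#: Cross-product norm (A^2) below which a plane triplet counts as collinear.
COLLINEAR_EPS = 1e-6


def unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} has (near-)zero length")
    return v / n


def plane_normal(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Unit normal of the plane through three points: normalize((p2-p1) x (p3-p1)).

    Raises :class:`DegenerateGeometryError` when the points are collinear
    (cross-product norm below ``COLLINEAR_EPS``).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    cross = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(cross)
    if norm < COLLINEAR_EPS:
        raise DegenerateGeometryError(
            f"collinear plane triplet (cross-product norm {norm:.2e} A^2)"
        )
    return cross / norm


def angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees, [0, 180], clamped against rounding."""
    u1 = unit(v1, "first vector")
    u2 = unit(v2, "second vector")
    cos = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


def fold_to_quadrant(angle_deg: float) -> float:
    """Center an angle into [0, 90]: values above 90 map to 180 - angle."""
    a = float(angle_deg)
    return 180.0 - a if a > 90.0 else a


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < COLLINEAR_EPS or np.linalg.norm(n2) < COLLINEAR_EPS:
        raise DegenerateGeometryError("dihedral undefined: three consecutive atoms collinear")
    m = np.cross(n1, unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    return Rotation.from_rotvec(np.radians(angle_deg) * unit(axis, "rotation axis")).as_matrix()


def rotate_about_line(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` with direction ``axis``."""
    R = rotation_about_axis(axis, angle_deg)
    origin = np.asarray(origin, dtype=float)
    return (np.asarray(points, dtype=float) - origin) @ R.T + origin


def random_rigid_transform(rng: np.random.Generator, translation_scale: float = 50.0):
    """A uniformly random proper rotation and a Gaussian translation (test helper)."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=translation_scale, size=3)
    return R, t
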