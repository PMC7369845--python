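"""Small vector-geometry helpers shared by perception and detection.

All coordinates are in Angstrom, all angles in degrees.
"""

from __future__ import annotations

import numpy as np

#: slack on inclusive threshold comparisons; planted boundary geometries
#: (e.g. an H...A pair at exactly 3.2 A) must not be lost to binary rounding.
EPS = 1e-9


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` of the triangle a-b-c, in degrees [0, 180]."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees [0, 180]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: zero vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring normals folded to [0, 90] degrees.

    Ring normal sign is arbitrary (depends on atom traversal order), so the
    angle is reported on the unsigned convention.
    """
    theta = vector_angle(n1, n2)
    return theta if theta <= 90.0 else 180.0 - theta


def plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane through >=3 points.

    Returns (centroid, unit normal, RMS out-of-plane deviation).
    """
    coords = np.asarray(coords, float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # normal = left singular vector of the smallest singular value
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rms


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
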