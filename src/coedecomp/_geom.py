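"""Low-level vector geometry shared by the backbone builder and dihedral code."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["dihedral", "bond_angle", "place_atom", "rotation_matrix"]


def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention.

    Accepts single points (shape (3,)) or stacked arrays (..., 3); the
    angle is positive for a clockwise rotation of p3 relative to p0 when
    looking down the p1->p2 axis, and lies in (-180, 180].
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = -np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    if ang.ndim == 0:
        return float(ang)
    return ang


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from internal coordinates relative to chain A-B-C.

    Natural-extension-reference-frame construction: D is placed at distance
    ``bond`` from C, with angle B-C-D ``angle_deg`` and torsion A-B-C-D
    ``torsion_deg``.
    """
    # scalar math: this sits in the generator's innermost loop
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    dx = -bond * math.cos(theta)
    dy = bond * math.sin(theta) * math.cos(chi)
    dz = bond * math.sin(theta) * math.sin(chi)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return np.array([
        c[0] + bcx * dx + mx * dy + nx * dz,
        c[1] + bcy * dx + my * dy + ny * dz,
        c[2] + bcz * dx + mz * dy + nz * dz,
    ])


def rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    k = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)
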