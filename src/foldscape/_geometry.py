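"""Small vector-geometry toolbox shared across modules.

Everything here operates on plain numpy arrays in nanometres and degrees;
no domain objects, so the routines double as independent building blocks
for tests.
"""

from __future__ import annotations

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` near-uniform unit vectors on the sphere (deterministic).

    Uses the Fibonacci/golden-spiral lattice, the standard quadrature for
    dot-surface (Shrake-Rupley style) area estimates.
    """
    if n < 1:
        raise ValueError("need at least one dot")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = GOLDEN_ANGLE * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rmsd, rotation, t_mobile, t_reference)`` where the aligned
    mobile coordinates are ``(mobile - t_mobile) @ rotation + t_reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets differ in shape")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = p @ rot - q
    rmsd = float(np.sqrt((diff * diff).sum() / mobile.shape[0]))
    return rmsd, rot, cm, cr


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180].

    cis = 0, trans = 180; positive for a clockwise rotation of the far bond
    when sighting down p1->p2.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond_length,
    angle(b,c,d) = bond_angle and dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(bond_angle)
    tor = np.radians(torsion)
    d_local = bond_length * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack((bc, m, n))
    return c + frame @ d_local


def pairwise_min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum Euclidean distance between two point sets."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=-1)).min())


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rotation about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
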