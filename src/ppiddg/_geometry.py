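"""Low-level vector geometry: dihedrals, internal-coordinate atom placement."""

from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to ``c`` by the NeRF construction.

    ``bond`` is |c-D|, ``angle_deg`` the b-c-D angle and ``torsion_deg``
    the a-b-c-D dihedral.
    """
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealised CB position from backbone N, CA, C (L-configuration).

    Linear-combination reconstruction commonly used to add a virtual CB
    to glycine; reproduces the tetrahedral ~110 deg N-CA-CB geometry.
    """
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv + ca


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
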