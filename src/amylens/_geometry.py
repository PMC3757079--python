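"""Low-level backbone geometry: NeRF atom placement, dihedrals, ideal bond table.

All lengths in Angstrom, all angles in degrees at the public surface
(radians internally where noted).
"""

from __future__ import annotations

import math

import numpy as np

# Ideal backbone geometry (Engh-Huber-like values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.01
BOND_CA_CB = 1.53

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.4


def place_fast(ax, ay, az, bx, by, bz, cx, cy, cz,
               bond, angle_deg, torsion_deg):
    """Scalar NeRF placement; returns the (x, y, z) tuple of atom D.

    Plain-float arithmetic: this sits in the inner loop of chain
    construction and closure refinement.
    """
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-10:
        raise ValueError("collinear predecessors for atom placement")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    st = math.sin(theta)
    d0 = -bond * math.cos(theta)
    d1 = bond * st * math.cos(chi)
    d2 = bond * st * math.sin(chi)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from predecessors A-B-C by natural extension (NeRF).

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``torsion_deg``
    the A-B-C-D dihedral.
    """
    return np.array(place_fast(
        a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2],
        bond, angle_deg, torsion_deg,
    ))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def wrap_angle(x):
    """Wrap angle(s) in degrees into (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


def angular_distance(a, b):
    """Smallest absolute separation of two angles in degrees."""
    return np.abs(wrap_angle(np.asarray(a) - np.asarray(b)))


def amide_h_fast(nx, ny, nz, cax, cay, caz, cpx, cpy, cpz):
    """Scalar amide-H reconstruction; see ``reconstruct_amide_h``."""
    ux, uy, uz = cpx - nx, cpy - ny, cpz - nz
    inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux * inv, uy * inv, uz * inv
    vx, vy, vz = cax - nx, cay - ny, caz - nz
    inv = 1.0 / math.sqrt(vx * vx + vy * vy + vz * vz)
    vx, vy, vz = vx * inv, vy * inv, vz * inv
    dx, dy, dz = -(ux + vx), -(uy + vy), -(uz + vz)
    inv = BOND_N_H / math.sqrt(dx * dx + dy * dy + dz * dz)
    return (nx + dx * inv, ny + dy * inv, nz + dz * inv)


def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Amide hydrogen position for residue i from N(i), CA(i), C(i-1).

    H lies in the C(i-1)-N-CA plane, 1.01 A from N, opposite the bisector
    of the two N-neighbor bonds.
    """
    return np.array(amide_h_fast(
        n[0], n[1], n[2], ca[0], ca[1], ca[2],
        c_prev[0], c_prev[1], c_prev[2],
    ))


_CB_COS = math.cos(math.radians(54.75))  # lift out of the backbone plane
_CB_SIN = math.sin(math.radians(54.75))


def cbeta_fast(nx, ny, nz, cax, cay, caz, cx, cy, cz):
    """Scalar ideal tetrahedral C-beta placement."""
    ux, uy, uz = nx - cax, ny - cay, nz - caz
    inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux * inv, uy * inv, uz * inv
    vx, vy, vz = cx - cax, cy - cay, cz - caz
    inv = 1.0 / math.sqrt(vx * vx + vy * vy + vz * vz)
    vx, vy, vz = vx * inv, vy * inv, vz * inv
    bx, by, bz = -(ux + vx), -(uy + vy), -(uz + vz)
    inv = 1.0 / math.sqrt(bx * bx + by * by + bz * bz)
    bx, by, bz = bx * inv, by * inv, bz * inv
    ox = vy * uz - vz * uy
    oy = vz * ux - vx * uz
    oz = vx * uy - vy * ux
    inv = 1.0 / math.sqrt(ox * ox + oy * oy + oz * oz)
    ox, oy, oz = ox * inv, oy * inv, oz * inv
    dx = _CB_COS * bx + _CB_SIN * ox
    dy = _CB_COS * by + _CB_SIN * oy
    dz = _CB_COS * bz + _CB_SIN * oz
    return (cax + BOND_CA_CB * dx, cay + BOND_CA_CB * dy, caz + BOND_CA_CB * dz)


def place_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N, CA, C."""
    return np.array(cbeta_fast(
        n[0], n[1], n[2], ca[0], ca[1], ca[2], c[0], c[1], c[2],
    ))
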