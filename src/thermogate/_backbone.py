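"""Internal-coordinate protein backbone machinery.

NeRF-style atom placement from (bond, angle, torsion) triples, extraction of
internal coordinates from Cartesian models, and cyclic-coordinate-descent
(CCD) chain closure.  Used by the loop-perturbation sampler in
:mod:`thermogate.ensemble` and the bundle generators in
:mod:`thermogate.synth`.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone geometry (Engh & Huber averages), Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.5
TORSION_N_C_CA_CB = 122.5


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given predecessors a-b-c such that |cd| = bond,
    angle(b, c, d) = angle and dihedral(a, b, c, d) = torsion (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle),
         np.sin(angle) * np.cos(torsion),
         -np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
             d: np.ndarray) -> float:
    """Dihedral angle a-b-c-d in degrees, in (−180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def internal_coords(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                    d: np.ndarray) -> tuple[float, float, float]:
    """(bond, angle, torsion) of atom d relative to predecessors a-b-c."""
    return (
        float(np.linalg.norm(d - c)),
        bond_angle(b, c, d),
        dihedral(a, b, c, d),
    )


def rotate_about_bond(points: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``points`` by ``angle`` (radians) about the line through
    ``origin`` with direction ``axis``."""
    u = axis / np.linalg.norm(axis)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return (points - origin) @ rot.T + origin


def ccd_optimal_angle(axis_origin: np.ndarray, axis_dir: np.ndarray,
                      moving: np.ndarray, targets: np.ndarray) -> float:
    """Rotation angle about the bond axis minimising the summed squared
    distance of ``moving`` points to ``targets`` (Canutescu & Dunbrack)."""
    u = axis_dir / np.linalg.norm(axis_dir)
    a = 0.0
    b = 0.0
    for m, t in zip(moving, targets):
        rel = m - axis_origin
        along = np.dot(rel, u) * u
        radial = rel - along
        r_len = np.linalg.norm(radial)
        if r_len < 1e-12:
            continue
        r_hat = radial / r_len
        s_hat = np.cross(u, r_hat)
        f = t - (axis_origin + along)
        a += r_len * np.dot(f, r_hat)
        b += r_len * np.dot(f, s_hat)
    if a == 0.0 and b == 0.0:
        return 0.0
    return float(np.arctan2(b, a))


def build_chain(seed_atoms: np.ndarray,
                internal: list[tuple[float, float, float]]) -> np.ndarray:
    """Extend a chain atom by atom from three seed atoms.

    ``internal[k]`` is the (bond, angle, torsion) of atom k relative to the
    three previously placed atoms.  Returns the (len(internal), 3) array of
    new positions.
    """
    atoms = [seed_atoms[0], seed_atoms[1], seed_atoms[2]]
    out = []
    for bond, angle, torsion in internal:
        d = place_atom(atoms[-3], atoms[-2], atoms[-1], bond, angle, torsion)
        atoms.append(d)
        out.append(d)
    return np.array(out)


def helix_backbone(n_res: int, phi_psi: list[tuple[float, float]] | None = None,
                   omega: float = 180.0) -> np.ndarray:
    """Backbone (N, CA, C) coordinates for a chain with given φ/ψ torsions.

    ``phi_psi`` is one (φ, ψ) pair per residue (default: ideal α-helix
    −57°/−47° throughout).  Returns an (n_res·3, 3) array in the order
    N1, CA1, C1, N2, ...
    """
    if phi_psi is None:
        phi_psi = [(-57.0, -47.0)] * n_res
    if len(phi_psi) != n_res:
        raise ValueError("need one (phi, psi) pair per residue")
    # Seed: residue 1 placed explicitly.
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([BOND_N_CA, 0.0, 0.0])
    c1 = place_atom(np.array([-1.0, 1.0, 0.0]), n1, ca1,
                    BOND_CA_C, ANGLE_N_CA_C, phi_psi[0][0])
    atoms = [n1, ca1, c1]
    for j in range(1, n_res):
        psi_prev = phi_psi[j - 1][1]
        phi = phi_psi[j][0]
        n = place_atom(atoms[-3], atoms[-2], atoms[-1],
                       BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(atoms[-2], atoms[-1], n,
                        BOND_N_CA, ANGLE_C_N_CA, omega)
        c = place_atom(atoms[-1], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms.extend([n, ca, c])
    return np.array(atoms)


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
             bond: float = BOND_CA_CB, angle: float = ANGLE_C_CA_CB,
             torsion: float = TORSION_N_C_CA_CB) -> np.ndarray:
    """Cβ position from the backbone frame of a residue."""
    return place_atom(n, c, ca, bond, angle, torsion)


def place_o(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray,
            bond: float = BOND_C_O, angle: float = ANGLE_CA_C_O,
            torsion: float = 180.0) -> np.ndarray:
    """Carbonyl O position, trans to the next residue's N."""
    return place_atom(n_next, ca, c, bond, angle, torsion)
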