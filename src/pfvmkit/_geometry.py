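"""Low-level vector geometry: dihedrals, bend angles, internal-coordinate
chain building (NeRF) and rigid superposition.

All angles are in degrees; torsions follow the IUPAC right-handed sign
convention and live in (-180, 180].
"""

from __future__ import annotations

import numpy as np

# Standard backbone internal coordinates (Engh & Huber averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, 0.0 for degenerate geometry."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-9:
        return 0.0
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        return 0.0  # collinear stretch: torsion undefined
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bend_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Planar angle at p1 in degrees, in [0, 180]."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 0.0
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position atom d given a-b-c and internal coordinates of c-d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Build an N-CA-C backbone for len(phi_psi) residues from (phi, psi)
    torsions with ideal bond geometry and trans peptide bonds.

    phi of the first residue and psi of the last are ignored (undefined).
    Returns an (n_res, 3, 3) array of N, CA, C coordinates.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    atoms = np.zeros((n_res, 3, 3))
    # seed the first residue in a canonical frame
    atoms[0, 0] = [0.0, 0.0, 0.0]
    atoms[0, 1] = [BOND_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        n_i = place_atom(atoms[i - 1, 0], atoms[i - 1, 1], atoms[i - 1, 2],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(atoms[i - 1, 1], atoms[i - 1, 2], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = place_atom(atoms[i - 1, 2], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, phi)
        atoms[i, 0], atoms[i, 1], atoms[i, 2] = n_i, ca_i, c_i
    return atoms


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto target.

    Returns (rotation matrix R, translation t, rmsd) such that
    mobile @ R.T + t best fits target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 paired points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = tc - r @ mc
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd
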