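"""Ideal coarse-grained backbone geometry and rigid-body superposition.

The model keeps three beads per residue (CA, CB, O); every other position
needed by the energy terms (the amide N used for hydrogen bonding, the
virtual CB of glycine) is reconstructed from ideal backbone geometry as a
fixed linear/geometric combination of the stored beads.
"""

from __future__ import annotations

import numpy as np

# Virtual Calpha-Calpha bond length (Å) of a trans peptide.
BOND_CA_CA = 3.8
# Calpha-Cbeta bond length (Å).
BOND_CA_CB = 1.53

# Carbonyl O placed in the local backbone frame between CA(i) and CA(i+1):
# O = CA_i + O_ALONG * (CA_{i+1} - CA_i) + O_PERP * w_hat, with w_hat the
# in-plane unit vector perpendicular to the bond.  The two constants are
# chosen so that |CA_i - O_i| ~ 2.40 Å and |O_i - CA_{i+1}| ~ 2.76 Å, the
# values found in real trans peptide planes.
O_ALONG = 0.4356
O_PERP = 1.738
BOND_CA_O = float(np.hypot(O_ALONG * BOND_CA_CA, O_PERP))      # ~2.400
BOND_O_CA_NEXT = float(np.hypot((1 - O_ALONG) * BOND_CA_CA, O_PERP))  # ~2.761

# Amide N of residue i reconstructed from CA(i-1), CA(i) and O(i-1) by fixed
# ideal-geometry coefficients (standard three-bead reconstruction), rescaled
# to a true affine combination (coefficients sum exactly to 1).
_N_SUM = 0.48318 + 0.70328 - 0.18643
N_COEFF_CA_PREV = 0.48318 / _N_SUM
N_COEFF_CA = 0.70328 / _N_SUM
N_COEFF_O_PREV = -0.18643 / _N_SUM

# CB direction coefficients: CB = CA + BOND_CA_CB * unit(CB_M * m + CB_N * n)
# where m is the (u - v) bisector of the two flanking CA bonds and n their
# right-handed normal; the normal component fixes the handedness (L side).
CB_M = 0.6
CB_N = 0.8


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n == 0.0, 1.0, n)


def _extended_ca(ca: np.ndarray) -> np.ndarray:
    """CA trace padded with one virtual residue at each end.

    The virtual positions copy the second bond at each terminus so that the
    local frames (u, v) stay well defined for terminal residues.
    """
    first = ca[0] - (ca[2] - ca[1])
    last = ca[-1] + (ca[-2] - ca[-3])
    return np.vstack([first, ca, last])


def local_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-residue unit vectors (u, v, n): incoming bond, outgoing bond, normal."""
    ext = _extended_ca(np.asarray(ca, float))
    u = _unit(ext[1:-1] - ext[:-2])
    v = _unit(ext[2:] - ext[1:-1])
    n = np.cross(u, v)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    # collinear bonds: fall back to any perpendicular
    bad = nn[:, 0] < 1e-8
    if np.any(bad):
        alt = np.cross(u[bad], np.array([0.12, 0.74, 0.66]))
        n[bad] = alt
        nn = np.linalg.norm(n, axis=-1, keepdims=True)
    return u, v, n / nn


def place_virtual_cb(ca: np.ndarray) -> np.ndarray:
    """Ideal CB positions for a CA trace (used for glycine / generated chains)."""
    u, v, n = local_frames(ca)
    direction = _unit(CB_M * _unit(u - v) + CB_N * n)
    return np.asarray(ca, float) + BOND_CA_CB * direction


def place_virtual_o(ca: np.ndarray) -> np.ndarray:
    """Ideal carbonyl O positions for a CA trace.

    O(i) sits between CA(i) and CA(i+1); the last residue reuses its
    incoming-bond direction as a straight-chain extrapolation.
    """
    ca = np.asarray(ca, float)
    _, v, n = local_frames(ca)
    w = _unit(np.cross(n, v))
    nxt = np.empty_like(ca)
    nxt[:-1] = ca[1:]
    nxt[-1] = ca[-1] + (ca[-2] - ca[-3])  # matches the extrapolated frame
    bond = nxt - ca
    # keep the stated geometry even if the actual bond deviates from 3.8 Å
    return ca + O_ALONG * bond + O_PERP * w


def amide_n_positions(ca: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Virtual amide N for residues 1..n-1 (residue 0 has no preceding O).

    Returns an (n, 3) array whose row 0 is NaN.
    """
    ca = np.asarray(ca, float)
    o = np.asarray(o, float)
    npos = np.full_like(ca, np.nan)
    npos[1:] = (N_COEFF_CA_PREV * ca[:-1]
                + N_COEFF_CA * ca[1:]
                + N_COEFF_O_PREV * o[:-1])
    return npos


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the RMSD (Å).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    moved = mc @ rot
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tc) ** 2, axis=1))))
    return moved + target.mean(axis=0), rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    """Best-fit (Kabsch) CA RMSD between two coordinate sets."""
    return kabsch_superpose(a, b)[1]
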