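"""Low-level 3-D geometry: internal-coordinate atom placement, dihedrals,
and least-squares rigid superposition (Kabsch).

Conventions: coordinates in Angstrom, angles in degrees, dihedrals in
(-180, 180] with the IUPAC sign convention.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1)
    b1 = unit(np.asarray(p2, dtype=float) - np.asarray(p1))
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position of atom d with given c-d bond length, b-c-d angle and
    a-b-c-d torsion (natural-extension reference frame construction)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = unit(np.asarray(c) - np.asarray(b))
    n = unit(np.cross(np.asarray(b) - np.asarray(a), bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            np.sin(angle) * np.sin(torsion),
        ]
    )
    return np.asarray(c) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid transform (R, t) mapping ``mobile`` onto ``reference``.

    Least-squares over proper rotations (reflections excluded).  Apply as
    ``mobile @ R.T + t``.  Raises on degenerate (coincident/collinear)
    selections of fewer than 3 points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("selections must be matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) atom selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = mu_r - r @ mu_m
    return r, t


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` over ``selection`` indices.

    The transform is fitted on the selected atoms but applied to all of
    ``mobile``.  Returns ``(R, t, transformed, rmsd_over_selection)``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        sel_m, sel_r = mobile[selection], reference[selection]
    r, t = kabsch(sel_m, sel_r)
    moved = mobile @ r.T + t
    sel_moved = moved if selection is None else moved[selection]
    return r, t, moved, rmsd(sel_moved, sel_r)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting) between matching (n, 3) arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
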