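"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in the package has a generator here that produces its
input with the answer known by construction: an ideal-helix coordinate
builder (for dihedral, H-bond and NOE round trips), shift tables with
injected secondary-structure offsets (for CSI recovery), r^-6 NOE volumes
from known coordinates (for calibration round trips), a spherical
tail-core/head-shell micelle with a placed peptide (for RDF and contact
analysis), and Gaussian positional jitter around a reference model (for
RMSF recovery).  All generators are pure functions of their parameters and
one explicit integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .constants import ONE_TO_THREE
from .geometry import place_atom, unit
from .micelle import Trajectory
from .noe import NOEPeak
from .peptide import PeptideSequence, parse_sequence
from .shifts import RandomCoilSet, ShiftTable
from .ensemble import StructureEnsemble

import pandas as pd

# Standard backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_N_H, _B_CA_CB = 1.231, 1.010, 1.532
_B_CA_H = 1.090
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def build_ideal_helix(
    seq: PeptideSequence | str,
    phi: float | np.ndarray = -57.0,
    psi: float | np.ndarray = -47.0,
) -> struc.AtomArray:
    """Backbone model of ``seq`` with the given (phi, psi) and omega = 180.

    ``phi`` and ``psi`` may be scalars (uniform conformation) or length-n
    arrays of per-residue dihedrals (phi[0] is unused: residue 1 has no
    phi).  Standard bond lengths and angles; atoms N, CA, C, O per
    residue, amide H on residues 2..n (except proline), alpha protons, and
    a CB stub on non-glycines.  The default dihedrals are the canonical
    alpha-helix, for which the i -> i+4 O..N distances fall in the
    2.8-3.2 A hydrogen-bonding range.
    """
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    n = len(seq)
    if n < 4:
        raise ValueError("helix builder needs at least 4 residues")
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    psi_arr = np.broadcast_to(np.asarray(psi, dtype=float), (n,))
    ncac = np.zeros((n, 3, 3))  # N, CA, C per residue
    ncac[0, 0] = (0.0, 0.0, 0.0)
    ncac[0, 1] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    ncac[0, 2] = ncac[0, 1] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        n_prev, ca_prev, c_prev = ncac[i - 1]
        ni = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi_arr[i - 1])
        cai = place_atom(ca_prev, c_prev, ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        ci = place_atom(c_prev, ni, cai, _B_CA_C, _A_N_CA_C, phi_arr[i])
        ncac[i] = (ni, cai, ci)

    atoms = []

    def add(res_idx, name, coord):
        atoms.append(
            struc.Atom(
                coord,
                atom_name=name,
                res_id=res_idx,
                res_name=ONE_TO_THREE[seq[res_idx]],
                chain_id="A",
                element=_element_of(name),
            )
        )

    for i in range(n):
        res = i + 1
        ni, cai, ci = ncac[i]
        add(res, "N", ni)
        add(res, "CA", cai)
        add(res, "C", ci)
        # carbonyl O anti to the next amide nitrogen
        add(res, "O", place_atom(ni, cai, ci, _B_C_O, _A_CA_C_O, psi_arr[i] + 180.0))
        if i > 0 and seq[res] != "P":
            h_dir = unit(unit(ni - ncac[i - 1, 2]) + unit(ni - cai))
            add(res, "H", ni + _B_N_H * h_dir)
        if seq[res] != "G":
            cb = _cb_position(ni, cai, ci)
            add(res, "CB", cb)
            t = [unit(x - cai) for x in (ni, ci, cb)]
            add(res, "HA", cai + _B_CA_H * unit(-(t[0] + t[1] + t[2])))
        else:
            cb = _cb_position(ni, cai, ci)  # virtual CB site -> HA2
            add(res, "HA2", cai + _B_CA_H * unit(cb - cai))
            t = [unit(x - cai) for x in (ni, ci, cb)]
            add(res, "HA3", cai + _B_CA_H * unit(-(t[0] + t[1] + t[2])))
    return struc.array(atoms)


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB stub with L-amino-acid chirality."""
    t1 = unit(n - ca)
    t2 = unit(c - ca)
    bisector = unit(t1 + t2)
    perp = unit(np.cross(t1, t2))
    gamma = math.radians(51.9)  # gives ~110.5 deg N-CA-CB and C-CA-CB
    direction = -bisector * math.cos(gamma) + perp * math.sin(gamma)
    return ca + _B_CA_CB * unit(direction)


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Ground truth for a synthetic alpha-proton CSD profile."""

    sequence: str
    segments: tuple = ()          # ((start, end, label), ...)
    helix_offset: float = -0.35   # ppm, typical helical Halpha deviation
    strand_offset: float = 0.35   # ppm
    noise_sigma: float = 0.0      # ppm
    seed: int = 0

    def label_of(self, residue: int) -> str:
        for start, end, label in self.segments:
            if start <= residue <= end:
                return label
        return "coil"


def synth_shift_table(spec: HelixSpec, rc: RandomCoilSet | None = None) -> ShiftTable:
    """Shift table with delta_obs = delta_rc + offset(label) + N(0, sigma).

    Glycine emits two alpha-proton rows (HA2/HA3), each independently
    noisy; amide rows are emitted at the random-coil value plus noise
    (prolines have none).  Deterministic under a fixed seed.
    """
    if rc is None:
        rc = RandomCoilSet()
    seq = parse_sequence(spec.sequence)
    offsets = {"helix": spec.helix_offset, "strand": spec.strand_offset, "coil": 0.0}
    rng = np.random.default_rng(spec.seed)
    rows = []
    for idx, aa in seq:
        off = offsets[spec.label_of(idx)]
        ha_labels = ("HA2", "HA3") if aa == "G" else ("HA",)
        for lab in ha_labels:
            rows.append(
                {
                    "residue": idx, "aa": aa, "atom": lab,
                    "shift_ppm": rc.ha[aa] + off
                    + rng.normal(0.0, spec.noise_sigma),
                }
            )
        if rc.hn[aa] is not None:
            rows.append(
                {
                    "residue": idx, "aa": aa, "atom": "HN",
                    "shift_ppm": rc.hn[aa] + rng.normal(0.0, spec.noise_sigma),
                }
            )
    return ShiftTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# NOE volumes
# ---------------------------------------------------------------------------

def synth_noe_volumes(
    model: struc.AtomArray,
    pairs,
    k: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> list[NOEPeak]:
    """Cross-peak volumes V = k * r^-6 * (1 + N(0, noise)) from a model.

    ``pairs`` is a list of (res_i, atom_i, res_j, atom_j); a pair farther
    apart than 6 A (the NOE observability limit) is rejected.
    """
    rng = np.random.default_rng(seed)
    peaks = []
    for res_i, atom_i, res_j, atom_j in pairs:
        a = _atom_coord(model, res_i, atom_i)
        b = _atom_coord(model, res_j, atom_j)
        r = float(np.linalg.norm(a - b))
        if r > 6.0:
            raise ValueError(
                f"pair {res_i}/{atom_i}-{res_j}/{atom_j} at {r:.2f} A exceeds 6 A"
            )
        volume = k * r**-6 * (1.0 + rng.normal(0.0, noise))
        peaks.append(NOEPeak(res_i, atom_i, res_j, atom_j, volume=float(volume)))
    return peaks


def _atom_coord(model: struc.AtomArray, res_id: int, name: str) -> np.ndarray:
    hits = np.flatnonzero((model.res_id == res_id) & (model.atom_name == name))
    if hits.size == 0:
        raise KeyError(f"atom {name} of residue {res_id} not in model")
    return model.coord[hits[0]]


# ---------------------------------------------------------------------------
# Micelle system and trajectories
# ---------------------------------------------------------------------------

def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``axis`` to +z (Rodrigues)."""
    a = unit(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def synth_micelle_system(
    n_tail: int,
    radius: float,
    peptide: struc.AtomArray,
    placement: str = "surface",
    seed: int = 0,
    n_head: int | None = None,
) -> tuple[struc.AtomArray, np.ndarray]:
    """One frame of a peptide + spherical micelle system, with role tags.

    Tail (aliphatic-core) atoms are uniform in a sphere of the given
    radius; headgroup atoms sit on a shell 1.5 A outside it.  The peptide
    is rotated so its principal (helix) axis is tangent to the micelle
    surface and translated to the surface (``placement="surface"``), or
    centred on the micelle's centre of mass (``placement="center"``).
    Returns ``(frame, roles)``.
    """
    if n_tail < 10:
        raise ValueError("need at least 10 tail atoms")
    if radius <= 5.0:
        raise ValueError("micelle radius must exceed 5 A")
    if n_head is None:
        n_head = max(10, n_tail // 4)
    rng = np.random.default_rng(seed)

    # uniform in sphere: direction uniform, radius ~ R * u^(1/3)
    def _directions(m):
        v = rng.normal(size=(m, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    tail_xyz = _directions(n_tail) * (
        radius * rng.uniform(size=(n_tail, 1)) ** (1.0 / 3.0)
    )
    head_xyz = _directions(n_head) * (radius + 1.5)

    ca = peptide.coord[peptide.atom_name == "CA"]
    centroid = ca.mean(axis=0)
    coords = peptide.coord - centroid
    # principal axis of the CA trace
    _, _, vt = np.linalg.svd(ca - centroid)
    rot = _rotation_to_z(vt[0])
    coords = coords @ rot.T
    if placement == "surface":
        coords = coords + np.array([radius + 1.0, 0.0, 0.0])
    elif placement == "center":
        extent = float(np.max(np.linalg.norm(ca - centroid, axis=1)))
        if extent > radius:
            raise ValueError("peptide larger than the micelle sphere")
    else:
        raise ValueError(f"unknown placement {placement!r}")

    atoms = []
    for atom, xyz in zip(peptide, coords):
        atoms.append(
            struc.Atom(
                xyz,
                atom_name=atom.atom_name,
                res_id=atom.res_id,
                res_name=atom.res_name,
                chain_id="A",
                element=atom.element,
            )
        )
    max_res = int(peptide.res_id.max())
    for i, xyz in enumerate(tail_xyz):
        atoms.append(
            struc.Atom(
                xyz, atom_name="C1", res_id=max_res + 1 + i,
                res_name="SDS", chain_id="M", element="C",
            )
        )
    for i, xyz in enumerate(head_xyz):
        atoms.append(
            struc.Atom(
                xyz, atom_name="O1", res_id=max_res + 1 + n_tail + i,
                res_name="SDS", chain_id="M", element="O",
            )
        )
    frame = struc.array(atoms)
    roles = np.array(
        ["peptide"] * len(peptide) + ["tail"] * n_tail + ["head"] * n_head,
        dtype=object,
    ).astype(str)
    return frame, roles


@dataclass(frozen=True)
class JitterSpec:
    """Gaussian positional jitter around a reference model.

    ``sigma`` is either a scalar (A, every atom) or a mapping
    res_id -> sigma; atoms of residues absent from the mapping stay fixed.
    Jitter is isotropic and frame-independent (no autocorrelation).
    """

    sigma: object = 0.5
    n_frames: int = 100
    seed: int = 0

    def sigma_for(self, res_ids: np.ndarray) -> np.ndarray:
        if np.isscalar(self.sigma):
            return np.full(len(res_ids), float(self.sigma))
        return np.array([float(self.sigma.get(int(r), 0.0)) for r in res_ids])


def synth_trajectory(
    reference: struc.AtomArray,
    spec: JitterSpec,
    roles: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory of ``n_frames`` independent Gaussian perturbations.

    Frame t = reference + N(0, sigma(residue)) applied per atom
    coordinate.  Deterministic under the spec's seed.
    """
    if spec.n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(spec.seed)
    sigma = spec.sigma_for(reference.res_id)[None, :, None]
    base = reference.coord[None, :, :]
    noise = rng.normal(size=(spec.n_frames, len(reference), 3)) * sigma
    frames = []
    for t in range(spec.n_frames):
        model = reference.copy()
        model.coord = (base + noise)[t]
        frames.append(model)
    ens = StructureEnsemble(struc.stack(frames))
    if roles is None:
        roles = np.array(["peptide"] * len(reference), dtype=object).astype(str)
    return Trajectory(ens, roles)
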