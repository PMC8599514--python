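"""Multi-model structure-ensemble statistics.

An NMR structure calculation deposits an ensemble of models of the same
molecule.  This module loads such ensembles from multi-model PDB files and
computes the descriptive statistics used to report them: per-segment
ensemble RMSD (each model against the iteratively converged ensemble
average), the medoid model, a hydrogen-bond-energy (Kabsch-Sander style)
secondary-structure assignment, and Ramachandran dihedral classes.

Containers are `biotite` atom arrays; :class:`StructureEnsemble` is a thin
wrapper around an ``AtomArrayStack`` that enforces a shared atom table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .geometry import dihedral, kabsch, rmsd, superpose, unit

BACKBONE_ATOMS = ("N", "CA", "C", "O")
CHAIN_BREAK_CA_CA = 4.5  # Angstrom
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_Q1Q2_F = 0.084 * 332.0  # DSSP electrostatic H-bond model constant


class StructureEnsemble:
    """M models over one shared atom table (names, residues, elements)."""

    def __init__(self, stack: struc.AtomArrayStack):
        if stack.stack_depth() < 1:
            raise ValueError("ensemble must contain at least one model")
        if not np.all(np.isfinite(stack.coord)):
            raise ValueError("non-finite coordinates in ensemble")
        self.stack = stack

    # -- accessors ---------------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.stack.stack_depth()

    @property
    def coords(self) -> np.ndarray:
        """(M, N, 3) coordinates in Angstrom."""
        return self.stack.coord

    @property
    def atom_names(self) -> np.ndarray:
        return self.stack.atom_name

    @property
    def res_ids(self) -> np.ndarray:
        return self.stack.res_id

    @property
    def res_names(self) -> np.ndarray:
        return self.stack.res_name

    @property
    def residues(self) -> list[int]:
        return sorted(set(self.stack.res_id.tolist()))

    def model(self, i: int) -> struc.AtomArray:
        """Model by 0-based index."""
        return self.stack[i]

    def select(self, residues=None, atom_names=None) -> np.ndarray:
        """Boolean atom mask by residue range/list and atom-name list."""
        mask = np.ones(self.stack.array_length(), dtype=bool)
        if residues is not None:
            mask &= np.isin(self.res_ids, np.asarray(list(residues)))
        if atom_names is not None:
            mask &= np.isin(self.atom_names, np.asarray(list(atom_names)))
        return mask

    def atom_index(self, res_id: int, atom_name: str) -> int:
        hits = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
        if hits.size == 0:
            raise KeyError(f"atom {atom_name} of residue {res_id} not in ensemble")
        return int(hits[0])

    @classmethod
    def from_models(cls, models: list[struc.AtomArray]) -> "StructureEnsemble":
        return cls(struc.stack(models))


def read_ensemble(path) -> StructureEnsemble:
    """Read a (multi-)model PDB file into a :class:`StructureEnsemble`.

    Alternate locations other than blank/'A' are dropped; hydrogens are
    retained.  Models with mismatched atom tables raise a ``ValueError``
    naming the mismatch.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises on inconsistent models
        raise ValueError(f"inconsistent models in {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    return StructureEnsemble(stack)


def write_ensemble(path, ens: StructureEnsemble) -> None:
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(ens.stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Segments and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """Named residue ranges x atom sets over which RMSDs are reported."""

    ranges: dict  # name -> (first_res, last_res) inclusive
    atom_sets: dict = field(
        default_factory=lambda: {
            "backbone": BACKBONE_ATOMS,
            "heavy": None,  # None = all non-hydrogen atoms
        }
    )

    @classmethod
    def standard(cls, n_residues: int, helix: tuple[int, int]) -> "SegmentSpec":
        """All / N-terminal / helix / C-terminal split around ``helix``."""
        h0, h1 = helix
        ranges = {"all": (1, n_residues)}
        if h0 > 1:
            ranges["n-terminal"] = (1, h0 - 1)
        ranges["helix"] = (h0, h1)
        if h1 < n_residues:
            ranges["c-terminal"] = (h1 + 1, n_residues)
        return cls(ranges=ranges)


def _atom_mask(ens: StructureEnsemble, residue_range, atom_names) -> np.ndarray:
    first, last = residue_range
    mask = (ens.res_ids >= first) & (ens.res_ids <= last)
    if atom_names is None:  # heavy atoms
        mask &= ens.stack.element != "H"
    else:
        mask &= np.isin(ens.atom_names, np.asarray(list(atom_names)))
    return mask


def _iterative_mean_fit(
    coords: np.ndarray, sel: np.ndarray, tol: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """Superpose all models onto their evolving average over ``sel`` atoms.

    Returns the fitted (M, N, 3) coordinates; the average over ``sel`` is
    converged to ``tol`` Angstrom.
    """
    fitted = coords.copy()
    mean = fitted[:, sel].mean(axis=0)
    for _ in range(max_iter):
        for m in range(fitted.shape[0]):
            r, t = kabsch(fitted[m, sel], mean)
            fitted[m] = fitted[m] @ r.T + t
        new_mean = fitted[:, sel].mean(axis=0)
        shift = float(np.sqrt(np.max(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return fitted


def ensemble_rmsd(
    ens: StructureEnsemble,
    spec: SegmentSpec,
    convention: str = "to-average",
) -> pd.DataFrame:
    """Per-segment, per-atom-set ensemble RMSD, mean +/- SD over models.

    ``convention="to-average"`` (default): each model is scored against the
    iteratively converged ensemble-average coordinates after superposition
    on the segment's atoms.  ``convention="pairwise"``: mean and SD of all
    M(M-1)/2 pairwise post-superposition RMSDs.
    """
    if ens.n_models < 2:
        raise ValueError("ensemble RMSD needs at least 2 models")
    if convention not in ("to-average", "pairwise"):
        raise ValueError(f"unknown convention {convention!r}")
    rows = []
    for set_name, atoms in spec.atom_sets.items():
        for seg_name, rng in spec.ranges.items():
            sel = _atom_mask(ens, rng, atoms)
            if not sel.any():
                raise ValueError(f"segment {seg_name}/{set_name} selects no atoms")
            idx = np.flatnonzero(sel)
            if convention == "to-average":
                fitted = _iterative_mean_fit(ens.coords, idx)
                mean = fitted[:, idx].mean(axis=0)
                values = [rmsd(fitted[m, idx], mean) for m in range(ens.n_models)]
            else:
                values = []
                for a in range(ens.n_models):
                    for b in range(a + 1, ens.n_models):
                        values.append(
                            superpose(ens.coords[a], ens.coords[b], idx)[3]
                        )
            rows.append(
                {
                    "atom_set": set_name,
                    "segment": seg_name,
                    "first_res": rng[0],
                    "last_res": rng[1],
                    "mean_rmsd": float(np.mean(values)),
                    "sd_rmsd": float(np.std(values, ddof=0)),
                }
            )
    return pd.DataFrame(rows)


def medoid(
    ens: StructureEnsemble,
    spec: SegmentSpec | None = None,
    segment: str = "all",
    atom_set: str = "backbone",
) -> int:
    """0-based index of the model minimising total pairwise RMSD.

    Pairwise RMSDs are computed after optimal superposition over the chosen
    segment's atom set; ties break to the lowest model index.
    """
    if spec is None:
        spec = SegmentSpec(ranges={"all": (min(ens.residues), max(ens.residues))})
    sel = np.flatnonzero(
        _atom_mask(ens, spec.ranges[segment], spec.atom_sets[atom_set])
    )
    m = ens.n_models
    if m == 1:
        return 0
    dist = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            d = superpose(ens.coords[a], ens.coords[b], sel)[3]
            dist[a, b] = dist[b, a] = d
    totals = dist.sum(axis=1)
    return int(np.argmin(totals))  # argmin takes the first (lowest) index on ties


# ---------------------------------------------------------------------------
# Secondary structure (hydrogen-bond energy method)
# ---------------------------------------------------------------------------

def _backbone_index(model: struc.AtomArray) -> dict:
    """Map residue id -> {atom_name: coord} for backbone atoms (+ H/HN)."""
    table: dict[int, dict[str, np.ndarray]] = {}
    for name in BACKBONE_ATOMS + ("H", "HN"):
        mask = model.atom_name == name
        for res, coord in zip(model.res_id[mask], model.coord[mask]):
            table.setdefault(int(res), {})[("H" if name == "HN" else name)] = coord
    return table


def _build_amide_h(table: dict, residues: list[int]) -> None:
    """Geometric amide-H reconstruction: 1.01 A from N, opposing the
    bisector of the C(i-1)-N and CA-N directions."""
    for prev, res in zip(residues, residues[1:]):
        atoms = table.get(res, {})
        prev_atoms = table.get(prev, {})
        if "H" in atoms or not {"N", "CA"} <= atoms.keys() or "C" not in prev_atoms:
            continue
        n = atoms["N"]
        direction = unit(unit(n - prev_atoms["C"]) + unit(n - atoms["CA"]))
        atoms["H"] = n + 1.01 * direction


def hbond_energy(c, o, n, h) -> float:
    """Electrostatic backbone H-bond energy (kcal/mol), DSSP formulation."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # overlapping atoms: no bond
        return 0.0
    return _HB_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def secondary_structure(
    model: struc.AtomArray, residue_types: dict | None = None
) -> dict:
    """Per-residue secondary-structure labels from backbone H-bond energies.

    A hydrogen bond is assigned between the C=O of residue i and the N-H of
    residue j when the electrostatic energy is below -0.5 kcal/mol.  Two or
    more consecutive i -> i+4 bonds define an alpha-helix over the spanned
    residues (label H); residues covered by an isolated i -> i+4 bond are
    turns (T); everything else is coil (C).  Prolines and residues missing
    backbone atoms cannot donate and are labelled from context only.
    Returns ``{residue_id: label}``.
    """
    table = _backbone_index(model)
    residues = sorted(table)
    _build_amide_h(table, residues)
    pro_res = set(
        int(r) for r in model.res_id[model.res_name == "PRO"].tolist()
    )
    bonded = []  # i with H-bond C=O(i) -> N-H(i+4)
    for i in residues:
        j = i + 4
        a, b = table.get(i, {}), table.get(j, {})
        if j in pro_res:
            continue
        if not {"C", "O"} <= a.keys() or not {"N", "H"} <= b.keys():
            continue
        if hbond_energy(a["C"], a["O"], b["N"], b["H"]) < HBOND_ENERGY_CUTOFF:
            bonded.append(i)
    labels = {r: "C" for r in residues}
    bonded_set = set(bonded)
    for i in bonded:
        span = range(i + 1, i + 5)
        if (i + 1) in bonded_set or (i - 1) in bonded_set:
            for r in span:
                if r in labels:
                    labels[r] = "H"
        else:
            for r in span:
                if r in labels and labels[r] != "H":
                    labels[r] = "T"
    return labels


def helix_span(labels: dict) -> tuple[int, int] | None:
    """First and last residue of the longest contiguous H run, or None."""
    runs: list[list[int]] = []
    prev = None
    for res in sorted(labels):
        if labels[res] == "H":
            if runs and prev == res - 1 and runs[-1][1] == prev:
                runs[-1][1] = res
            else:
                runs.append([res, res])
        prev = res
    if not runs:
        return None
    start, end = max(runs, key=lambda r: r[1] - r[0])
    return start, end


# ---------------------------------------------------------------------------
# Ramachandran analysis
# ---------------------------------------------------------------------------

_REGION_ORDER = ("favoured", "additional", "generous", "disallowed")


def _in_boxes(phi: float, psi: float, boxes) -> bool:
    return any(p0 <= phi <= p1 and s0 <= psi <= s1 for p0, p1, s0, s1 in boxes)


# Coarse rectangular approximations of the classic four-class phi/psi map.
_FAVOURED = [
    (-140.0, -40.0, -75.0, -5.0),    # alpha-helical core
    (-170.0, -50.0, 90.0, 180.0),    # beta core
    (-170.0, -50.0, -180.0, -160.0),  # beta core (wrapped)
]
_ADDITIONAL = [
    (-180.0, -20.0, -110.0, 45.0),
    (-180.0, -20.0, 60.0, 180.0),
    (-180.0, -20.0, -180.0, -140.0),
    (20.0, 100.0, -20.0, 90.0),       # left-handed helix
]
_GENEROUS = [
    (-180.0, 0.0, -180.0, 180.0),
    (0.0, 120.0, -60.0, 120.0),
]


def classify_phi_psi(phi: float, psi: float, is_glycine: bool = False) -> str:
    """Coarse four-class Ramachandran region of a (phi, psi) pair."""
    if _in_boxes(phi, psi, _FAVOURED):
        return "favoured"
    if _in_boxes(phi, psi, _ADDITIONAL):
        return "additional"
    if _in_boxes(phi, psi, _GENEROUS) or is_glycine:
        return "generous"
    return "disallowed"


def backbone_dihedrals(model: struc.AtomArray) -> pd.DataFrame:
    """Phi/psi per residue; NaN at termini and across chain breaks."""
    table = _backbone_index(model)
    residues = sorted(table)
    ca = {r: table[r].get("CA") for r in residues}
    rows = []
    for k, res in enumerate(residues):
        atoms = table[res]
        phi = psi = np.nan
        prev_res = residues[k - 1] if k > 0 else None
        next_res = residues[k + 1] if k + 1 < len(residues) else None

        def _contiguous(r1, r2):
            if r1 is None or r2 is None or r2 != r1 + 1:
                return False
            a, b = ca.get(r1), ca.get(r2)
            return (
                a is not None
                and b is not None
                and np.linalg.norm(a - b) <= CHAIN_BREAK_CA_CA
            )

        if _contiguous(prev_res, res) and {"N", "CA", "C"} <= atoms.keys() and "C" in table[prev_res]:
            phi = dihedral(table[prev_res]["C"], atoms["N"], atoms["CA"], atoms["C"])
        if _contiguous(res, next_res) and {"N", "CA", "C"} <= atoms.keys() and "N" in table[next_res]:
            psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], table[next_res]["N"])
        rows.append({"residue": res, "phi": phi, "psi": psi})
    return pd.DataFrame(rows)


def ramachandran(model: struc.AtomArray) -> tuple[pd.DataFrame, dict]:
    """Phi/psi dihedrals, per-residue region class, and class fractions.

    Residues lacking either dihedral (termini, chain breaks) are excluded
    from the fractions.  Glycine is never classed as disallowed.
    """
    frame = backbone_dihedrals(model)
    gly = set(int(r) for r in model.res_id[model.res_name == "GLY"].tolist())
    classes = []
    for _, row in frame.iterrows():
        if np.isnan(row["phi"]) or np.isnan(row["psi"]):
            classes.append(None)
        else:
            classes.append(
                classify_phi_psi(row["phi"], row["psi"], int(row["residue"]) in gly)
            )
    frame = frame.assign(region=classes)
    counted = [c for c in classes if c is not None]
    total = len(counted)
    fractions = {
        region: (counted.count(region) / total if total else np.nan)
        for region in _REGION_ORDER
    }
    return frame, fractions
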