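"""NOE cross-peak classification and distance-restraint calibration.

NOESY cross-peak volumes scale approximately as r^-6 with the interproton
distance (isolated spin-pair approximation), so a single reference pair of
known distance converts integrated volumes into upper distance bounds:
``r = r_ref * (V_ref / V) ** (1/6)``, clamped at an observability ceiling.
Connectivities are classified by atom kind and residue offset into the
standard sequential/medium/long-range NOE types; degenerate proton groups
receive Wuthrich pseudoatom corrections.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import ONE_TO_THREE, PSEUDOATOM_CORRECTION

DEFAULT_REF_DISTANCE = 1.78  # geminal methylene proton pair, Angstrom
DEFAULT_CEILING = 6.0        # NOE observability limit, Angstrom

RANGE_CLASSES = ("intraresidue", "sequential", "medium-range", "long-range")


@dataclass(frozen=True)
class NOEPeak:
    """One integrated NOESY cross-peak between two protons."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    volume: float

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("peak volume must be positive")
        if (self.res_i, self.atom_i) == (self.res_j, self.atom_j):
            raise ValueError("diagonal peak: both protons identical")


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper distance bound between two protons (or pseudoatoms)."""

    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    bound: float  # Angstrom
    range_class: str
    pseudoatom_corrected: bool = False

    def __post_init__(self):
        if self.bound <= 0:
            raise ValueError("distance bound must be positive")
        if self.range_class not in RANGE_CLASSES:
            raise ValueError(f"unknown range class {self.range_class!r}")


def range_class(offset: int) -> str:
    """Standard NMR range class from the residue-index offset |j - i|."""
    offset = abs(offset)
    if offset == 0:
        return "intraresidue"
    if offset == 1:
        return "sequential"
    if offset <= 4:
        return "medium-range"
    return "long-range"


def _atom_kind(label: str) -> str:
    if label in ("HN", "H"):
        return "N"
    if label.startswith("HA"):
        return "a"
    if label.startswith("HB"):
        return "b"
    if re.fullmatch(r"[HQ][A-Z0-9]*", label):
        return "other"
    return "unknown"


def classify_connectivity(peak: NOEPeak) -> tuple[str, str]:
    """NOE connectivity type and range class of a cross-peak.

    Types follow the usual d_XY(i, i+n) naming, e.g. ``daN(i,i+3)`` for an
    HA(i)-HN(i+3) peak or ``dNN(i,i+1)``.  Peaks whose atom kinds or offset
    fall outside the named set are typed ``other``; an unrecognisable atom
    label is also typed ``other`` (never silently dropped).
    """
    (ri, ai), (rj, aj) = sorted(
        [(peak.res_i, peak.atom_i), (peak.res_j, peak.atom_j)]
    )
    off = rj - ri
    kind_lo, kind_hi = _atom_kind(ai), _atom_kind(aj)
    cls = range_class(off)
    if "unknown" in (kind_lo, kind_hi):
        return "other", cls
    named = {
        ("N", "N", 1): "dNN(i,i+1)",
        ("a", "N", 1): "daN(i,i+1)",
        ("a", "N", 3): "daN(i,i+3)",
        ("a", "b", 3): "dab(i,i+3)",
        ("a", "N", 4): "daN(i,i+4)",
        ("a", "b", 4): "dab(i,i+4)",
        ("b", "b", 6): "dbb(i,i+6)",
    }
    return named.get((kind_lo, kind_hi, off), "other"), cls


def count_by_class(restraints) -> dict:
    """Counts as reported in structure statistics tables.

    ``nonsequential`` merges medium- and long-range; the three counts sum
    to the number of restraints.
    """
    counts = {"intraresidue": 0, "sequential": 0, "nonsequential": 0}
    for r in restraints:
        key = r.range_class
        if key in ("medium-range", "long-range"):
            key = "nonsequential"
        counts[key] += 1
    return counts


_GEMINAL = re.compile(r"^(.*[A-Z])(\d)$")


def is_fixed_distance(peak: NOEPeak) -> bool:
    """Covalently fixed proton pairs excluded from calibration.

    Geminal pairs (same residue, labels sharing a stem and differing in the
    trailing digit only, e.g. HB2/HB3) and aromatic ring neighbours (same
    residue, delta/epsilon ring protons).
    """
    if peak.res_i != peak.res_j:
        return False
    mi, mj = _GEMINAL.match(peak.atom_i), _GEMINAL.match(peak.atom_j)
    if mi and mj and mi.group(1) == mj.group(1):
        return True
    stems = {re.sub(r"\d+$", "", peak.atom_i), re.sub(r"\d+$", "", peak.atom_j)}
    return stems == {"HD", "HE"}


def calibrate(
    peaks,
    ref_distance: float = DEFAULT_REF_DISTANCE,
    ref_volume: float | None = None,
    ceiling: float = DEFAULT_CEILING,
    exclude_fixed: bool = True,
) -> list[DistanceRestraint]:
    """Convert peak volumes into upper distance bounds (single-constant
    r^-6 calibration).

    ``ref_volume`` defaults to the largest volume among excluded fixed
    pairs, the natural internal reference; if no fixed pair is present it
    must be given explicitly.  Bounds are clamped at ``ceiling``.
    """
    if not 1.7 <= ref_distance <= 3.0:
        raise ValueError("reference distance must lie in 1.7-3.0 Angstrom")
    peaks = list(peaks)
    fixed = [p for p in peaks if is_fixed_distance(p)]
    if ref_volume is None:
        if not fixed:
            raise ValueError(
                "no fixed-distance pair available; pass ref_volume explicitly"
            )
        ref_volume = max(p.volume for p in fixed)
    if ref_volume <= 0:
        raise ValueError("reference volume must be positive")
    out = []
    for p in peaks:
        if exclude_fixed and is_fixed_distance(p):
            continue
        bound = min(ref_distance * (ref_volume / p.volume) ** (1.0 / 6.0), ceiling)
        out.append(
            DistanceRestraint(
                p.res_i, p.atom_i, p.res_j, p.atom_j,
                bound=bound,
                range_class=range_class(p.res_j - p.res_i),
            )
        )
    return out


def apply_pseudoatom_correction(
    restraint: DistanceRestraint, degeneracy: str
) -> DistanceRestraint:
    """Widen a bound for a degenerate proton group (pseudoatom).

    ``degeneracy`` is one of methylene/methyl/isopropyl/aromatic-ring; a
    restraint may be corrected once only.
    """
    if restraint.pseudoatom_corrected:
        raise ValueError("restraint already pseudoatom-corrected")
    if degeneracy not in PSEUDOATOM_CORRECTION:
        raise ValueError(f"unknown degeneracy kind {degeneracy!r}")
    return replace(
        restraint,
        bound=restraint.bound + PSEUDOATOM_CORRECTION[degeneracy],
        pseudoatom_corrected=True,
    )


# ---------------------------------------------------------------------------
# Restraint checking against an ensemble
# ---------------------------------------------------------------------------

def _resolve(ens, res_id: int, label: str) -> np.ndarray:
    """(M, 3) coordinates of an atom, or the centroid of its proton set.

    Exact atom-name match first; otherwise all protons whose label starts
    with the given stem (pseudoatom convention, e.g. HB -> HB2/HB3).
    """
    exact = np.flatnonzero((ens.res_ids == res_id) & (ens.atom_names == label))
    if exact.size:
        return ens.coords[:, exact[0]]
    prefix = np.flatnonzero(
        (ens.res_ids == res_id)
        & np.char.startswith(ens.atom_names.astype(str), label)
    )
    if prefix.size == 0:
        raise KeyError(f"cannot resolve atom {label} of residue {res_id}")
    return ens.coords[:, prefix].mean(axis=1)


def violations(ens, restraints) -> pd.DataFrame:
    """Per-restraint distance statistics over an ensemble.

    Columns: mean/SD of the model distances, the maximum violation
    ``max(0, d - bound)`` over models, and the fraction of models
    violating the bound.
    """
    rows = []
    for r in restraints:
        a = _resolve(ens, r.res_i, r.atom_i)
        b = _resolve(ens, r.res_j, r.atom_j)
        d = np.linalg.norm(a - b, axis=1)
        viol = np.maximum(0.0, d - r.bound)
        rows.append(
            {
                "res_i": r.res_i, "atom_i": r.atom_i,
                "res_j": r.res_j, "atom_j": r.atom_j,
                "bound": r.bound,
                "mean_distance": float(d.mean()),
                "sd_distance": float(d.std(ddof=0)),
                "max_violation": float(viol.max()),
                "frac_violating": float((viol > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peak-list and .upl I/O
# ---------------------------------------------------------------------------

def read_peaks(path) -> list[NOEPeak]:
    """Read a TSV peak list (columns res_i/atom_i/res_j/atom_j/volume)."""
    frame = pd.read_csv(path, sep="\t")
    return [
        NOEPeak(int(r.res_i), str(r.atom_i), int(r.res_j), str(r.atom_j),
                float(r.volume))
        for r in frame.itertuples()
    ]


def write_upl(restraints, path, sequence=None) -> None:
    """Write CYANA-style .upl: resnum resname atom resnum resname atom bound.

    Residue names come from ``sequence`` (a PeptideSequence) when given,
    else are written as UNK.
    """
    def res_name(idx):
        if sequence is None:
            return "UNK"
        return ONE_TO_THREE[sequence[idx]]

    with open(path, "w") as fh:
        for r in restraints:
            fh.write(
                f"{r.res_i:>4d} {res_name(r.res_i):<4s} {r.atom_i:<5s}"
                f"{r.res_j:>4d} {res_name(r.res_j):<4s} {r.atom_j:<5s}"
                f"{r.bound:8.2f}\n"
            )


def read_upl(path) -> list[DistanceRestraint]:
    restraints = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7:
                continue
            ri, _, ai, rj, _, aj, bound = parts[:7]
            ri, rj = int(ri), int(rj)
            restraints.append(
                DistanceRestraint(
                    ri, ai, rj, aj,
                    bound=float(bound),
                    range_class=range_class(rj - ri),
                )
            )
    return restraints
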