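"""Chemical-shift-deviation (CSD) analysis for peptide 1H shifts.

Workflow: a :class:`ShiftTable` of observed shifts is compared against a
:class:`RandomCoilSet` baseline to produce a :class:`CSDProfile`
(``delta = obs - rc`` per residue).  From the amide-proton profile,
hydrogen-bond lengths are estimated with the empirical model
``delta = 19.2 * d**-3 - 2.3``; from the alpha-proton profile, secondary
structure is segmented with the chemical-shift-index run rule (four or more
consecutive residues at least 0.1 ppm upfield -> helix; three or more at
least 0.1 ppm downfield -> strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    HBOND_MODEL_A,
    HBOND_MODEL_B,
    RANDOM_COIL_HA,
    RANDOM_COIL_HN,
    STANDARD_AA,
)

__all__ = [
    "ShiftTable",
    "RandomCoilSet",
    "CSDProfile",
    "HBondProfile",
    "Segment",
    "SecondaryStructureSegments",
    "read_shift_table",
    "compute_csd",
    "hbond_lengths",
    "hbond_forward",
    "csi_segments",
    "csd_extrema",
]


class ShiftTable:
    """Per-residue, per-atom 1H chemical shifts.

    Wraps a DataFrame with columns ``residue`` (1-based int), ``aa``
    (one-letter code), ``atom`` (HN/HA/HA2/HB...), ``shift_ppm``.
    """

    COLUMNS = ("residue", "aa", "atom", "shift_ppm")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["residue"] = frame["residue"].astype(int)
        frame["shift_ppm"] = frame["shift_ppm"].astype(float)
        if ((frame["shift_ppm"] < 0) | (frame["shift_ppm"] > 12)).any():
            raise ValueError("1H shifts must lie within 0-12 ppm")
        if frame.duplicated(subset=["residue", "atom"]).any():
            dup = frame[frame.duplicated(subset=["residue", "atom"])].iloc[0]
            raise ValueError(
                f"duplicate shift for residue {dup['residue']} atom {dup['atom']}"
            )
        self.frame = frame.sort_values(["residue", "atom"], kind="stable").reset_index(
            drop=True
        )

    @property
    def residues(self) -> list[int]:
        return sorted(self.frame["residue"].unique().tolist())

    def residue_type(self, residue: int) -> str:
        rows = self.frame[self.frame["residue"] == residue]
        if rows.empty:
            raise KeyError(f"no shifts for residue {residue}")
        return rows["aa"].iloc[0]

    def shifts_for(self, residue: int, atom_prefix: str) -> np.ndarray:
        """All shifts of ``residue`` whose atom label starts with ``atom_prefix``."""
        rows = self.frame[
            (self.frame["residue"] == residue)
            & self.frame["atom"].str.startswith(atom_prefix)
        ]
        return rows["shift_ppm"].to_numpy()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


def read_shift_table(path) -> ShiftTable:
    """Read a TSV shift table (columns residue/aa/atom/shift_ppm)."""
    return ShiftTable(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class RandomCoilSet:
    """Random-coil 1H reference shifts per residue type."""

    hn: dict = field(default_factory=lambda: dict(RANDOM_COIL_HN))
    ha: dict = field(default_factory=lambda: dict(RANDOM_COIL_HA))
    provenance: str = "Wishart et al. (1995), water, reduced Cys"

    def __post_init__(self):
        for aa in STANDARD_AA:
            if aa not in self.ha:
                raise ValueError(f"random-coil set missing HA value for {aa}")
            if aa not in self.hn:
                raise ValueError(f"random-coil set missing HN entry for {aa}")

    @classmethod
    def from_tsv(cls, path) -> "RandomCoilSet":
        """Load a set from TSV with columns aa/hn/ha (hn blank for Pro)."""
        frame = pd.read_csv(path, sep="\t")
        hn = {
            row["aa"]: (None if pd.isna(row["hn"]) else float(row["hn"]))
            for _, row in frame.iterrows()
        }
        ha = {row["aa"]: float(row["ha"]) for _, row in frame.iterrows()}
        return cls(hn=hn, ha=ha, provenance=str(path))


@dataclass
class CSDProfile:
    """Per-residue chemical-shift deviation delta = obs - rc for one nucleus.

    ``delta`` is NaN wherever the nucleus is unobserved or inapplicable
    (e.g. proline HN); ``defined`` is the complementary mask.
    """

    nucleus: str
    residues: np.ndarray  # 1-based indices, contiguous 1..N
    aa: list[str]
    delta: np.ndarray     # ppm, NaN where undefined

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "aa": self.aa, "delta_ppm": self.delta}
        )


def compute_csd(
    shifts: ShiftTable, rc: RandomCoilSet | None = None, nucleus: str = "HA"
) -> CSDProfile:
    """Chemical-shift deviations for every residue present in the table.

    For ``nucleus="HA"`` glycine's two alpha protons (and any other
    degenerate HA pair) are averaged before the random-coil value is
    subtracted.  For ``nucleus="HN"`` prolines are masked (no amide proton).
    Residues lacking the requested nucleus are masked, never zero-filled.
    """
    if nucleus not in ("HN", "HA"):
        raise ValueError("nucleus must be 'HN' or 'HA'")
    if rc is None:
        rc = RandomCoilSet()
    first, last = min(shifts.residues), max(shifts.residues)
    index = np.arange(first, last + 1)
    delta = np.full(len(index), np.nan)
    aa_list = []
    for pos, residue in enumerate(index):
        try:
            aa = shifts.residue_type(residue)
        except KeyError:
            aa_list.append("?")
            continue
        aa_list.append(aa)
        if aa not in rc.ha:
            raise KeyError(f"residue type {aa} absent from random-coil set")
        if nucleus == "HN":
            ref = rc.hn[aa]
            if ref is None:  # proline
                continue
            # exact HN label only: excludes side-chain amides like HD21
            rows = shifts.frame[
                (shifts.frame["residue"] == residue) & (shifts.frame["atom"] == "HN")
            ]
            obs = rows["shift_ppm"].to_numpy()
        else:
            ref = rc.ha[aa]
            obs = shifts.shifts_for(residue, "HA")
        if obs.size == 0:
            continue
        delta[pos] = float(np.mean(obs)) - ref
    return CSDProfile(nucleus=nucleus, residues=index, aa=aa_list, delta=delta)


def hbond_forward(d: np.ndarray | float) -> np.ndarray | float:
    """Amide CSD predicted from hydrogen-bond length d (Angstrom)."""
    return HBOND_MODEL_A * np.asarray(d, dtype=float) ** -3 - HBOND_MODEL_B


@dataclass
class HBondProfile:
    """Per-residue amide hydrogen-bond length estimate (Angstrom)."""

    residues: np.ndarray
    d_n: np.ndarray  # NaN where the CSD is undefined or out of model domain
    model_a: float = HBOND_MODEL_A
    model_b: float = HBOND_MODEL_B

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "d_N_A": self.d_n})


def hbond_lengths(amide_csd: CSDProfile) -> HBondProfile:
    """Invert delta = 19.2 d^-3 - 2.3 to hydrogen-bond lengths.

    ``d = (19.2 / (delta + 2.3)) ** (1/3)``; residues with
    ``delta <= -2.3`` fall outside the model domain and stay NaN.
    """
    if amide_csd.nucleus != "HN":
        raise ValueError("hydrogen-bond lengths require the amide (HN) profile")
    shifted = amide_csd.delta + HBOND_MODEL_B
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(shifted > 0, (HBOND_MODEL_A / shifted) ** (1.0 / 3.0), np.nan)
    return HBondProfile(residues=amide_csd.residues.copy(), d_n=d)


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based, inclusive
    end: int    # inclusive
    label: str  # helix / strand / coil

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class SecondaryStructureSegments:
    """Non-overlapping, ascending residue segments covering the profile."""

    segments: list[Segment]

    @property
    def helices(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "helix"]

    @property
    def strands(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "strand"]

    def label_of(self, residue: int) -> str:
        for s in self.segments:
            if s.start <= residue <= s.end:
                return s.label
        raise KeyError(f"residue {residue} outside segmentation")


def _maximal_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (0-based, inclusive) of maximal True runs."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def csi_segments(
    alpha_csd: CSDProfile,
    helix_thresh: float = -0.1,
    strand_thresh: float = 0.1,
    helix_min: int = 4,
    strand_min: int = 3,
) -> SecondaryStructureSegments:
    """Run-rule secondary-structure segmentation of an alpha-proton profile.

    Maximal runs of consecutive residues with ``delta <= helix_thresh`` and
    length >= ``helix_min`` are labelled helix; runs with
    ``delta >= strand_thresh`` of length >= ``strand_min`` are labelled
    strand; every other residue is coil.  Undefined (masked) residues break
    runs and are labelled coil.  Helix and strand runs cannot overlap
    because the thresholds are disjoint.
    """
    if alpha_csd.nucleus != "HA":
        raise ValueError("CSI segmentation requires the alpha-proton profile")
    delta = alpha_csd.delta
    labels = np.array(["coil"] * len(delta), dtype=object)
    defined = alpha_csd.defined
    for flags, min_len, name in (
        (defined & (delta <= helix_thresh), helix_min, "helix"),
        (defined & (delta >= strand_thresh), strand_min, "strand"),
    ):
        for i0, i1 in _maximal_runs(flags):
            if i1 - i0 + 1 >= min_len:
                labels[i0 : i1 + 1] = name
    segments = []
    res = alpha_csd.residues
    for i0, i1 in _runs_of_equal(labels):
        segments.append(Segment(int(res[i0]), int(res[i1]), str(labels[i0])))
    return SecondaryStructureSegments(segments)


def _runs_of_equal(labels: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - 1))
            start = i
    return runs


def csd_extrema(csd: CSDProfile) -> dict:
    """Strict local extrema of a CSD profile and the spacing between maxima.

    A defined residue is a local maximum (minimum) iff strictly greater
    (less) than both of its nearest *defined* neighbours; plateaus yield no
    extremum.  Returns ``{"maxima": [...], "minima": [...],
    "max_spacings": [...]}`` with 1-based residue indices.
    """
    idx = np.flatnonzero(csd.defined)
    if idx.size < 3:
        raise ValueError("need at least 3 defined residues")
    values = csd.delta[idx]
    residues = csd.residues[idx]
    maxima, minima = [], []
    for k in range(1, len(idx) - 1):
        if values[k] > values[k - 1] and values[k] > values[k + 1]:
            maxima.append(int(residues[k]))
        elif values[k] < values[k - 1] and values[k] < values[k + 1]:
            minima.append(int(residues[k]))
    spacings = [b - a for a, b in zip(maxima, maxima[1:])]
    return {"maxima": maxima, "minima": minima, "max_spacings": spacings}
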