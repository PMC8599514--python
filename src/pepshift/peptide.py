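"""Peptide sequence handling: parsing, composition, mass and amphipathicity.

The central object is :class:`PeptideSequence`, a validated, 1-based-indexed
one-letter sequence.  On top of it sit the small pieces of arithmetic that a
solution-NMR study needs before any spectrum is touched: molecular weight of
the (optionally disulfide-bridged) peptide, molar concentration of the NMR
sample, cysteine topology, and the helical hydrophobic moment used to
quantify amphipathicity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .constants import (
    DISULFIDE_MASS_LOSS,
    EISENBERG_HYDROPHOBICITY,
    POLARITY_CLASS,
    RESIDUE_MASS,
    STANDARD_AA,
    WATER_MASS,
)


@dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide sequence with 1-based residue numbering.

    ``seq[k]`` with a 1-based ``k`` returns the one-letter code of residue
    ``k``; iteration yields ``(index, code)`` pairs.
    """

    residues: tuple[str, ...]

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError("sequence must contain at least one residue")
        for pos, code in enumerate(self.residues, start=1):
            if code not in STANDARD_AA:
                raise ValueError(
                    f"non-standard residue {code!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index: int) -> str:
        if not 1 <= index <= len(self):
            raise IndexError(f"residue index {index} outside 1..{len(self)}")
        return self.residues[index - 1]

    def __iter__(self):
        return iter(enumerate(self.residues, start=1))

    def __str__(self) -> str:
        return "".join(self.residues)


def parse_sequence(text: str) -> PeptideSequence:
    """Parse a bare one-letter string or single-record FASTA into a sequence.

    FASTA header lines (starting ``>``) and all whitespace are discarded;
    lower-case letters are accepted and upper-cased.  A non-standard letter
    raises :class:`ValueError` naming its (1-based) position in the cleaned
    sequence.
    """
    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith(">")]
    cleaned = "".join("".join(lines).split()).upper()
    if not cleaned:
        raise ValueError("empty sequence")
    return PeptideSequence(tuple(cleaned))


def composition(seq: PeptideSequence) -> dict[str, int]:
    """Residue-type counts over all 20 standard types (zeros included)."""
    counts = Counter(code for _, code in seq)
    return {aa: counts.get(aa, 0) for aa in STANDARD_AA}


def average_mass(seq: PeptideSequence, n_disulfides: int = 0) -> float:
    """Average molecular weight of the peptide in g/mol.

    Sum of average residue masses plus one water, minus 2.016 g/mol (two
    hydrogens) per disulfide bridge.  ``n_disulfides`` may not exceed the
    number of formable bridges, ``floor(#Cys / 2)``.
    """
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    n_cys = sum(1 for _, code in seq if code == "C")
    if n_disulfides > n_cys // 2:
        raise ValueError(
            f"{n_disulfides} disulfide(s) impossible with {n_cys} cysteine(s)"
        )
    total = sum(RESIDUE_MASS[code] for _, code in seq) + WATER_MASS
    return total - DISULFIDE_MASS_LOSS * n_disulfides


def molar_concentration(mass_mg: float, volume_mL: float, mw: float) -> float:
    """Concentration in mM of ``mass_mg`` of peptide in ``volume_mL`` solvent."""
    if mass_mg <= 0 or volume_mL <= 0 or mw <= 0:
        raise ValueError("mass, volume and molecular weight must be positive")
    return mass_mg / (mw * volume_mL) * 1000.0


def cysteine_positions(seq: PeptideSequence) -> list[int]:
    """Ascending 1-based positions of all cysteines."""
    return [idx for idx, code in seq if code == "C"]


def hydrophobic_moment(
    seq: PeptideSequence,
    start: int = 1,
    end: int | None = None,
    twist_deg: float = 100.0,
    scale: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Helical hydrophobic moment of residues ``start..end`` (inclusive).

    Each residue contributes a vector of length equal to its hydrophobicity
    pointing at angle ``k * twist_deg`` (k counted from the window start);
    100 deg/residue is the ideal alpha-helical twist.  Returns
    ``(magnitude, direction_deg)`` of the vector sum; the magnitude is the
    standard Eisenberg mu_H for the window.
    """
    if end is None:
        end = len(seq)
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"window {start}..{end} outside sequence 1..{len(seq)}")
    h = scale if scale is not None else EISENBERG_HYDROPHOBICITY
    twist = math.radians(twist_deg)
    x = sum(h[seq[k]] * math.cos((k - start) * twist) for k in range(start, end + 1))
    y = sum(h[seq[k]] * math.sin((k - start) * twist) for k in range(start, end + 1))
    return math.hypot(x, y), math.degrees(math.atan2(y, x))


def polarity_classes(seq: PeptideSequence) -> list[str]:
    """Per-residue coarse polarity class (hydrophobic/polar/cationic/...)."""
    return [POLARITY_CLASS[code] for _, code in seq]
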