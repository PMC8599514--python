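"""Bundled reference data.

The package ships the assigned 1H chemical shifts of palustrin-Ca
(GFLDIIKDTGKEFAVKILNNLKCKLAGGCPP), a 31-residue host-defence peptide from
*Lithobates catesbeianus*, measured in a 50/50 water/TFE-d3 mixture.  These
are the worked-example inputs for the chemical-shift pipeline.
"""

from __future__ import annotations

from importlib import resources

from .peptide import PeptideSequence, parse_sequence
from .shifts import ShiftTable, read_shift_table

PALUSTRIN_CA = "GFLDIIKDTGKEFAVKILNNLKCKLAGGCPP"


def palustrin_ca_sequence() -> PeptideSequence:
    """The palustrin-Ca peptide sequence (31 residues)."""
    return parse_sequence(PALUSTRIN_CA)


def palustrin_ca_shifts() -> ShiftTable:
    """Assigned 1H chemical shifts of palustrin-Ca in 50% TFE-d3/water.

    The Gly1 amide proton is absent (unobservable due to chemical
    exchange); prolines 30-31 have no amide proton.
    """
    ref = resources.files("pepshift.data") / "palustrin_ca_shifts.tsv"
    with resources.as_file(ref) as path:
        return read_shift_table(path)
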