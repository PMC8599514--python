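"""Peptide-micelle trajectory analysis: radial distribution functions,
backbone RMSF, and contact fractions.

A trajectory is an ordered set of frames over one fixed atom table; each
atom carries a role tag (``peptide``, ``head`` or ``tail``) distinguishing
peptide atoms from micelle headgroup and aliphatic-tail atoms.  The system
is finite (a single micelle in solution), so the radial distribution
function is normalised against a uniform reference density inside the
``max_r`` sphere rather than a periodic bulk density: uniformly distributed
partners give g(r) ~ 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import StructureEnsemble, read_ensemble
from .geometry import kabsch

DEFAULT_DR = 0.1     # Angstrom, RDF bin width
DEFAULT_MAX_R = 25.0  # Angstrom, RDF range
BACKBONE = ("N", "CA", "C", "O")
ROLES = ("peptide", "head", "tail")


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom table with role tags."""

    ensemble: StructureEnsemble          # frames stored as models
    roles: np.ndarray                    # per-atom role tag
    frame_spacing: str = "1 frame"

    def __post_init__(self):
        if len(self.roles) != self.ensemble.stack.array_length():
            raise ValueError("role tags must cover every atom")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown role tags: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.ensemble.n_models

    @property
    def coords(self) -> np.ndarray:
        return self.ensemble.coords

    def atom_mask(self, role=None, residues=None, atom_names=None,
                  elements=None) -> np.ndarray:
        mask = np.ones(len(self.roles), dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if residues is not None:
            mask &= np.isin(self.ensemble.res_ids, np.asarray(list(residues)))
        if atom_names is not None:
            mask &= np.isin(self.ensemble.atom_names, np.asarray(list(atom_names)))
        if elements is not None:
            mask &= np.isin(self.ensemble.stack.element, np.asarray(list(elements)))
        return mask

    def peptide_residues(self) -> list[int]:
        pep = self.roles == "peptide"
        return sorted(set(self.ensemble.res_ids[pep].tolist()))

    def tail_frames(self, fraction: float) -> "Trajectory":
        """Trailing ``fraction`` of frames (production window of a run)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        start = int(np.ceil(self.n_frames * (1 - fraction)))
        start = min(start, self.n_frames - 1)
        return Trajectory(
            StructureEnsemble(self.ensemble.stack[start:]),
            self.roles,
            self.frame_spacing,
        )


def read_trajectory(pdb_path, roles_path) -> Trajectory:
    """Multi-model PDB frames plus a TSV role file (atom_index -> role).

    Atom indices in the role file are 0-based positions in the PDB atom
    table.
    """
    ens = read_ensemble(pdb_path)
    frame = pd.read_csv(roles_path, sep="\t")
    roles = np.array(["peptide"] * ens.stack.array_length(), dtype=object)
    roles[frame["atom_index"].to_numpy()] = frame["role"].to_numpy()
    return Trajectory(ens, roles.astype(str))


def write_roles(traj: Trajectory, path) -> None:
    pd.DataFrame(
        {"atom_index": np.arange(len(traj.roles)), "role": traj.roles}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RDFProfile:
    """Binned g(r) for one residue against a partner atom selection."""

    residue: int
    edges: np.ndarray   # bin edges, length n_bins + 1
    g: np.ndarray       # g(r) per bin
    n_pairs: int
    n_frames: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue, "r": self.centers, "g": self.g}
        )


def pair_rdf(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    dr: float = DEFAULT_DR,
    max_r: float = DEFAULT_MAX_R,
) -> tuple[np.ndarray, np.ndarray]:
    """g(r) between two atom selections over frames.

    ``coords_a``/``coords_b`` are (F, n_a, 3) and (F, n_b, 3).  The mean
    per-frame pair count in shell [r, r+dr) is divided by the count a
    uniform distribution of the n_a * n_b pairs inside the ``max_r`` sphere
    would give (shell volume 4 pi r_mid^2 dr over sphere volume
    4/3 pi max_r^3), so uncorrelated selections give g ~ 1.  No periodic
    images: the system is a finite micelle.
    """
    if dr <= 0 or max_r <= dr:
        raise ValueError("need dr > 0 and max_r > dr")
    if coords_a.shape[1] == 0 or coords_b.shape[1] == 0:
        raise ValueError("empty atom selection")
    n_bins = int(round(max_r / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    counts = np.zeros(n_bins)
    n_frames = coords_a.shape[0]
    for f in range(n_frames):
        d = np.linalg.norm(
            coords_a[f][:, None, :] - coords_b[f][None, :, :], axis=-1
        ).ravel()
        counts += np.histogram(d, bins=edges)[0]
    mean_counts = counts / n_frames
    n_pairs = coords_a.shape[1] * coords_b.shape[1]
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_mid**2 * dr
    v_ref = (4.0 / 3.0) * np.pi * max_r**3
    expected = n_pairs * shell / v_ref
    g = mean_counts / expected
    return edges, g


def residue_rdf(
    traj: Trajectory,
    residue: int,
    dr: float = DEFAULT_DR,
    max_r: float = DEFAULT_MAX_R,
    heavy_only: bool = False,
    tail_fraction: float | None = None,
) -> RDFProfile:
    """g(r) between one peptide residue's carbon atoms and the micelle
    tail (aliphatic, non-sulfate) atoms.

    ``heavy_only`` restricts the partner selection to carbons; otherwise
    tail hydrogens are included.  ``tail_fraction`` restricts the average
    to the trailing fraction of frames.
    """
    if tail_fraction is not None:
        traj = traj.tail_frames(tail_fraction)
    sel_a = traj.atom_mask(role="peptide", residues=[residue], elements=["C"])
    if heavy_only:
        sel_b = traj.atom_mask(role="tail", elements=["C"])
    else:
        sel_b = traj.atom_mask(role="tail")
    if not sel_a.any():
        raise ValueError(f"residue {residue} has no carbon atoms")
    if not sel_b.any():
        raise ValueError("no micelle tail atoms in trajectory")
    edges, g = pair_rdf(
        traj.coords[:, sel_a], traj.coords[:, sel_b], dr=dr, max_r=max_r
    )
    return RDFProfile(
        residue=residue,
        edges=edges,
        g=g,
        n_pairs=int(sel_a.sum() * sel_b.sum()),
        n_frames=traj.n_frames,
    )


@dataclass
class RMSFProfile:
    """Per-residue backbone root-mean-square fluctuation, Angstrom."""

    residues: np.ndarray
    rmsf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "rmsf_A": self.rmsf})


def rmsf(traj: Trajectory, atom_names=BACKBONE) -> RMSFProfile:
    """Backbone RMSF per peptide residue.

    Every frame is superposed (fit over the selected peptide atoms) onto
    the mean structure, the mean is recomputed once, and
    ``RMSF = sqrt(<|x - <x>|^2>)`` is averaged over frames and over each
    residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = traj.atom_mask(role="peptide", atom_names=atom_names)
    if not sel.any():
        raise ValueError("selection matches no peptide atoms")
    idx = np.flatnonzero(sel)
    coords = traj.coords.astype(np.float64)
    mean = coords[:, idx].mean(axis=0)
    for f in range(traj.n_frames):
        r, t = kabsch(coords[f, idx], mean)
        coords[f] = coords[f] @ r.T + t
    mean = coords[:, idx].mean(axis=0)
    sq_disp = np.sum((coords[:, idx] - mean) ** 2, axis=-1)  # (F, n_sel)
    res_of_sel = traj.ensemble.res_ids[idx]
    residues = np.array(traj.peptide_residues())
    values = np.array(
        [np.sqrt(sq_disp[:, res_of_sel == r].mean()) for r in residues]
    )
    return RMSFProfile(residues=residues, rmsf=values)


def contact_summary(traj: Trajectory, cutoff: float = 4.5) -> pd.DataFrame:
    """Per-residue fraction of frames with any residue carbon within
    ``cutoff`` of a micelle tail atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tail = traj.atom_mask(role="tail")
    rows = []
    for res in traj.peptide_residues():
        sel = traj.atom_mask(role="peptide", residues=[res], elements=["C"])
        if not sel.any():
            rows.append({"residue": res, "contact_fraction": np.nan})
            continue
        hits = 0
        for f in range(traj.n_frames):
            d = np.linalg.norm(
                traj.coords[f][sel][:, None, :] - traj.coords[f][tail][None, :, :],
                axis=-1,
            )
            if d.min() < cutoff:
                hits += 1
        rows.append({"residue": res, "contact_fraction": hits / traj.n_frames})
    return pd.DataFrame(rows)
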