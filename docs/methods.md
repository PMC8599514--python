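# Methods

This note documents the models implemented in `pepshift`, the defaults
and conventions chosen where the field admits more than one, and what
the synthetic-data generators do and do not emulate.

## Sequence arithmetic

Molecular weights use average (isotope-abundance-weighted) residue
masses plus one water (18.0153 g/mol), minus 2.016 g/mol per disulfide
bridge. The default is the reduced peptide (`n_disulfides=0`), which is
how vendors typically quote synthetic-peptide masses; for palustrin-Ca
this gives 3303.97 ≈ 3304 g/mol. Molar concentration is
`mass_mg / (MW · volume_mL) · 1000` in mM.

The helical hydrophobic moment follows Eisenberg: residues contribute
vectors of length equal to their consensus-scale hydrophobicity at
angles of k·100° around the helix axis (100°/residue is the ideal
α-helical twist; the angle is a parameter). Adding a constant to the
scale changes the moment's magnitude, so the scale itself is part of
the definition; the Eisenberg consensus values are embedded.

## Chemical-shift deviations

Δδ = δ_obs − δ_rc per residue and nucleus (HN or Hα). The random-coil
reference is the Wishart et al. (1995) aqueous GGXGG set, embedded as
the default and overridable from TSV; cysteine uses the reduced-form
values. No solvent (TFE) correction is applied. Glycine's two Hα
resonances are averaged before subtraction; prolines are masked for
amide analysis, and residues without the requested resonance stay
masked (NaN) rather than zero-filled — downstream run detection treats
them as run breakers, not as coil evidence.

Choice to note: published CSD analyses rarely name their random-coil
set. Boundary residues of threshold runs can move by one position
between common sets (for the bundled table, the end of the first helix
run falls at Asp⁸ with some sets and at Lys⁷ with the Wishart values,
because Asp⁸'s deviation is −0.04 ppm — inside the ±0.1 ppm dead band).
Interior run boundaries (2, 11, 25 here) are robust to this choice.

## Hydrogen-bond lengths

Amide-proton deviations map to backbone hydrogen-bond lengths through
the empirical model Δδ = 19.2·d_N⁻³ − 2.3 (Δδ in ppm, d_N in Å),
inverted as d_N = (19.2/(Δδ + 2.3))^⅓. The model's domain requires
Δδ > −2.3 ppm; residues outside it are flagged undefined. The
forward/inverse pair is exact to 1e-9 relative tolerance over the
physically relevant 1.5–4.5 Å range.

## CSI segmentation

Maximal runs of consecutive defined residues with Δδ(Hα) ≤ −0.1 ppm and
length ≥ 4 are helices; runs with Δδ ≥ +0.1 ppm and length ≥ 3 are
strands; everything else is coil. Thresholds and minimum lengths are
parameters. Because the two thresholds are disjoint, no residue can
receive both labels; the output is a full partition of the profile.

## NOE calibration

Single-constant isolated-spin-pair calibration:
r = r_ref·(V_ref/V)^(1/6) with one reference pair (default: a geminal
methylene pair at 1.78 Å; the reference volume defaults to the largest
volume among the fixed-distance pairs in the list). Bounds are clamped
at 6.0 Å, the usual NOE observability ceiling. Covalently fixed pairs —
geminal protons and aromatic δ/ε ring neighbours — are excluded from
the restraint list. Per-class calibration curves (as in CALIBA) are not
implemented; the single-constant form is pinned by an exact round trip
against volumes generated as k·r⁻⁶ from known coordinates. Pseudoatom
corrections add the standard Wüthrich allowances (methylene and methyl
+1.0 Å, isopropyl +2.4 Å, aromatic ring +2.0 Å), at most once per
restraint. Range classes follow the standard convention: |i−j| = 0
intraresidue, 1 sequential, 2–4 medium-range, ≥ 5 long-range; summary
counts merge medium and long range as "nonsequential".

## Ensemble statistics

Superposition is the Kabsch least-squares rigid transform with proper
rotations enforced (validated against an independent solver of the same
Wahba problem). **Ensemble RMSD convention:** all models are superposed
onto the evolving ensemble-average coordinates over the segment's atom
set until the average moves < 1e-6 Å; reported values are mean ± SD
over models of each model's RMSD to that converged average. Published
tables do not always state whether they report model-to-average or
mean-pairwise values, so both are implemented; model-to-average is the
default. Backbone means N, CA, C, O; "heavy" means all non-hydrogens.
The medoid is the model minimising the summed pairwise
post-superposition RMSD, ties broken to the lowest model number.

Secondary structure uses the Kabsch–Sander electrostatic hydrogen-bond
energy, E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, with
a bond assigned below −0.5 kcal/mol; two or more consecutive i→i+4
bonds define a helix (H) over the spanned residues, an isolated i→i+4
bond marks a turn (T), everything else is coil. Strand (E) assignment
via β-bridge bookkeeping is not implemented — the target systems are
helical peptides. Missing amide protons are rebuilt 1.01 Å from N along
the direction opposing the bisector of the C(i−1)→N and CA→N bonds.
This is a DSSP-style assignment, not STRIDE: torsional-propensity terms
are omitted, which can move helix termini by about one residue.

Ramachandran classes come from an embedded coarse rectangular map
approximating the classic four-class (favoured / additionally allowed /
generously allowed / disallowed) scheme; glycine is never classed
disallowed. Because published percentages depend strongly on the exact
map polygons, per-class fractions from this map are indicative only and
are not comparable digit-for-digit with PROCHECK outputs. Dihedrals are
computed only where consecutive backbone atoms exist and the CA–CA
distance is ≤ 4.5 Å (chain-break rule); terminal residues lack φ or ψ
and are excluded from the fractions.

## Micelle-interaction analysis

The radial distribution function is computed between a residue's carbon
atoms and the micelle's aliphatic (non-sulfate) tail atoms, by default
including tail hydrogens (`heavy_only` restricts to carbons). Bins are
[r, r+δr) with defaults δr = 0.1 Å and max r = 25.0 Å (250 bins).
**Normalisation:** the mean per-frame pair count per shell is divided
by the count expected if the partner atoms were uniform in the max-r
sphere (shell volume 4π·r_mid²·δr over sphere volume (4/3)π·max r³), so
uncorrelated selections give g ≈ 1. A micelle in solution is a finite
object, not periodic bulk, so the bulk-density convention of
periodic-box MD tools is deliberately not used; with it, absolute g
values scale with the (unknowable, box-dependent) reference density,
while peak positions and shapes are unaffected. RDFs can be restricted
to the trailing fraction of frames (default 40% when requested),
mirroring the usual practice of analysing only the equilibrated tail of
a simulation.

RMSF superposes every frame onto the mean structure over the selected
peptide backbone atoms (mean recomputed once after fitting), then takes
√⟨|x − ⟨x⟩|²⟩ per residue over frames and that residue's atoms. For
isotropic per-coordinate jitter of width σ the expected value is σ√3.

Contact fractions report, per residue, the fraction of frames with any
residue carbon within a cutoff (default 4.5 Å) of a tail atom.

## Synthetic generators

All generators are pure functions of their parameters and one explicit
seed (numpy `default_rng`; no global state).

- **Ideal helix builder:** NeRF internal-coordinate chain with standard
  bond lengths/angles, ω = 180°, and uniform or per-residue (φ, ψ);
  default (−57°, −47°) gives i→i+4 O···N distances of ~3.1 Å and a
  1.5 Å/residue rise. Atoms: N, CA, C, O, amide H (not on Pro or
  residue 1), Hα (two for Gly), CB stub (L-chirality) on non-Gly.
  Computed dihedrals equal the inputs to < 1e-3°.
- **Shift tables:** δ_obs = δ_rc + offset(label) + N(0, σ) per residue;
  helix offset −0.35 ppm by default (a typical helical Hα deviation
  magnitude), coil 0. Glycine emits two Hα rows.
- **NOE volumes:** V = k·r⁻⁶·(1 + N(0, σ_rel)) from model coordinates;
  pairs beyond 6 Å are rejected.
- **Micelle system:** tail atoms uniform in a sphere (radius default
  chosen per test, ~14–16 Å, the size of an SDS micelle core), head
  atoms on a shell 1.5 Å outside, peptide placed with its principal
  axis tangent to the surface or at the centre.
- **Trajectories:** frame = reference + isotropic Gaussian displacement
  with per-residue amplitude; independent across frames.

What these do *not* emulate: solvent, realistic micelle packing,
autocorrelated dynamics, spin diffusion, ring-current shifts, or
assignment ambiguity. Passing the recovery suites therefore shows the
analysis chain is self-consistent and correctly implements its stated
models — not that those models capture every feature of experimental
spectra or trajectories.

## Problem sizes and tolerances

Tests run on 20–31-residue peptides, ensembles of 5–20 models,
trajectories of up to 2000 frames, and RDFs of a few hundred partner
atoms over tens of frames — sizes at which every stage's expected
behaviour is known in closed form or by exhaustive search. Statistical
recovery tolerances: CSI boundaries exact at σ = 0 and within ±1
residue in ≥ 95% of 200 replicates at σ = 0.02 ppm; RMSF within 5% of
σ√3 at 2000 frames; uniform-partner RDF within 0.1 of unity on bins
with ≥ 1000 expected counts (≈3% sampling error). Deterministic round
trips (H-bond model, NOE calibration, dihedrals, superposition) are
checked at 1e-6 or tighter.

## Known limitations

- Amide-CSD hydrogen-bond lengths inherit the empirical model's scatter;
  values for residues with Δδ near −2.3 ppm diverge and are flagged.
- The DSSP-style assignment lacks β-strand (E) and 3₁₀-helix classes.
- The Ramachandran map is coarse by design (see above).
- `.upl` reading ignores CYANA comment/weight extensions.
- Trajectory input is multi-model PDB only; binary trajectory formats
  are out of scope.
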