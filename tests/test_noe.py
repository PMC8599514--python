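"""NOE classification, calibration, pseudoatoms, .upl I/O, violations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepshift import noe, synth
from pepshift.noe import (
    DistanceRestraint,
    NOEPeak,
    apply_pseudoatom_correction,
    calibrate,
    classify_connectivity,
    count_by_class,
    is_fixed_distance,
    range_class,
    read_upl,
    violations,
    write_upl,
)
from pepshift.synth import JitterSpec


class TestClassification:
    @pytest.mark.parametrize(
        "peak,expect",
        [
            (NOEPeak(5, "HA", 8, "HN", 1.0), ("daN(i,i+3)", "medium-range")),
            (NOEPeak(5, "HN", 6, "HN", 1.0), ("dNN(i,i+1)", "sequential")),
            (NOEPeak(23, "HB2", 29, "HB3", 1.0), ("dbb(i,i+6)", "long-range")),
            (NOEPeak(4, "HA", 8, "HB2", 1.0), ("dab(i,i+4)", "medium-range")),
            (NOEPeak(3, "HA", 3, "HB2", 1.0), ("other", "intraresidue")),
        ],
    )
    def test_named_types(self, peak, expect):
        assert classify_connectivity(peak) == expect

    def test_reversed_peak_classifies_identically(self):
        a = NOEPeak(5, "HA", 8, "HN", 1.0)
        b = NOEPeak(8, "HN", 5, "HA", 1.0)
        assert classify_connectivity(a) == classify_connectivity(b)

    def test_unknown_label_is_other_not_dropped(self):
        typ, cls = classify_connectivity(NOEPeak(1, "XX9", 2, "HN", 1.0))
        assert typ == "other" and cls == "sequential"

    @given(st.integers(1, 31), st.integers(1, 31))
    @settings(derandomize=True, max_examples=60)
    def test_range_class_matches_offset_rule(self, i, j):
        cls = range_class(j - i)
        off = abs(j - i)
        brute = (
            "intraresidue" if off == 0
            else "sequential" if off == 1
            else "medium-range" if off <= 4
            else "long-range"
        )
        assert cls == brute


class TestCounts:
    def test_empty(self):
        assert count_by_class([]) == {
            "intraresidue": 0, "sequential": 0, "nonsequential": 0
        }

    def test_one_per_class(self):
        rs = [
            DistanceRestraint(1, "HA", 1, "HN", 3.0, "intraresidue"),
            DistanceRestraint(1, "HA", 2, "HN", 3.0, "sequential"),
            DistanceRestraint(1, "HA", 4, "HN", 3.0, "medium-range"),
            DistanceRestraint(1, "HA", 8, "HN", 3.0, "long-range"),
        ]
        assert count_by_class(rs) == {
            "intraresidue": 1, "sequential": 1, "nonsequential": 2
        }

    def test_known_mixture_recovered(self, rng):
        mixture = {"intraresidue": 14, "sequential": 25, "nonsequential": 9}
        rs = []
        for _ in range(mixture["intraresidue"]):
            rs.append(DistanceRestraint(3, "HA", 3, "HB2", 3.0, "intraresidue"))
        for _ in range(mixture["sequential"]):
            rs.append(DistanceRestraint(3, "HA", 4, "HN", 3.0, "sequential"))
        for _ in range(mixture["nonsequential"]):
            rs.append(DistanceRestraint(3, "HA", 7, "HN", 3.0, "medium-range"))
        counts = count_by_class(rs)
        assert counts == mixture
        assert sum(counts.values()) == len(rs)


class TestCalibrate:
    def test_reference_volume_identity(self):
        peaks = [NOEPeak(1, "HA", 2, "HN", 5.0)]
        (r,) = calibrate(peaks, ref_distance=2.2, ref_volume=5.0)
        assert r.bound == pytest.approx(2.2)

    def test_sixth_root_scaling(self):
        peaks = [NOEPeak(1, "HA", 2, "HN", 1.0 / 64.0)]
        (r,) = calibrate(peaks, ref_distance=1.78, ref_volume=1.0)
        assert r.bound == pytest.approx(3.56)

    def test_ceiling_applied(self):
        peaks = [NOEPeak(1, "HA", 9, "HN", 1e-9)]
        (r,) = calibrate(peaks, ref_distance=1.78, ref_volume=1.0)
        assert r.bound == 6.0

    def test_scale_invariance(self):
        peaks = [NOEPeak(1, "HA", 2, "HN", v) for v in (0.5, 2.0, 7.0)]
        a = calibrate(peaks, ref_volume=1.0)
        scaled = [NOEPeak(p.res_i, p.atom_i, p.res_j, p.atom_j, p.volume * 13.7)
                  for p in peaks]
        b = calibrate(scaled, ref_volume=13.7)
        assert [r.bound for r in a] == pytest.approx([r.bound for r in b])

    def test_bound_monotone_decreasing_in_volume(self):
        vols = [0.1, 0.5, 1.0, 4.0]
        peaks = [NOEPeak(1, "HA", 2, "HN", v) for v in vols]
        bounds = [r.bound for r in calibrate(peaks, ref_volume=1.0)]
        assert bounds == sorted(bounds, reverse=True)

    def test_fixed_distance_pairs_excluded(self):
        peaks = [
            NOEPeak(3, "HB2", 3, "HB3", 9.0),   # geminal
            NOEPeak(2, "HD", 2, "HE", 4.0),     # aromatic ring neighbours
            NOEPeak(1, "HA", 2, "HN", 1.0),
        ]
        out = calibrate(peaks)  # ref volume from the geminal pair
        assert len(out) == 1
        assert out[0].bound == pytest.approx(1.78 * 9.0 ** (1 / 6))

    def test_round_trip_from_helix(self, ideal_helix, palustrin_seq):
        seq = str(palustrin_seq)
        pairs = [
            (i, "HA", i + 3, "H")
            for i in range(2, 25)
            if seq[i - 1] != "G" and seq[i + 2] != "P"
        ]
        peaks = synth.synth_noe_volumes(ideal_helix, pairs, k=3.7)
        rest = calibrate(peaks, ref_distance=2.5, ref_volume=3.7 * 2.5**-6)
        for (ri, ai, rj, aj), r in zip(pairs, rest):
            a = ideal_helix.coord[
                (ideal_helix.res_id == ri) & (ideal_helix.atom_name == ai)
            ][0]
            b = ideal_helix.coord[
                (ideal_helix.res_id == rj) & (ideal_helix.atom_name == aj)
            ][0]
            assert r.bound == pytest.approx(float(np.linalg.norm(a - b)), abs=1e-6)

    def test_bad_reference_distance(self):
        with pytest.raises(ValueError):
            calibrate([NOEPeak(1, "HA", 2, "HN", 1.0)], ref_distance=5.0,
                      ref_volume=1.0)


class TestPseudoatoms:
    @pytest.mark.parametrize(
        "kind,delta", [("methylene", 1.0), ("methyl", 1.0),
                       ("isopropyl", 2.4), ("aromatic-ring", 2.0)]
    )
    def test_corrections(self, kind, delta):
        r = DistanceRestraint(1, "QB", 5, "HN", 3.5, "medium-range")
        out = apply_pseudoatom_correction(r, kind)
        assert out.bound == pytest.approx(3.5 + delta)
        assert out.pseudoatom_corrected

    def test_no_double_correction(self):
        r = DistanceRestraint(1, "QB", 5, "HN", 3.5, "medium-range",
                              pseudoatom_corrected=True)
        with pytest.raises(ValueError):
            apply_pseudoatom_correction(r, "methyl")

    def test_unknown_kind(self):
        r = DistanceRestraint(1, "QB", 5, "HN", 3.5, "medium-range")
        with pytest.raises(ValueError):
            apply_pseudoatom_correction(r, "septet")


class TestViolations:
    def test_satisfied_and_violated(self, ideal_helix):
        traj = synth.synth_trajectory(ideal_helix, JitterSpec(sigma=0.0, n_frames=3))
        ens = traj.ensemble
        a = ideal_helix.coord[
            (ideal_helix.res_id == 5) & (ideal_helix.atom_name == "HA")
        ][0]
        b = ideal_helix.coord[
            (ideal_helix.res_id == 8) & (ideal_helix.atom_name == "H")
        ][0]
        d = float(np.linalg.norm(a - b))
        rs = [
            DistanceRestraint(5, "HA", 8, "H", d + 0.5, "medium-range"),
            DistanceRestraint(5, "HA", 8, "H", d - 0.5, "medium-range"),
        ]
        out = violations(ens, rs)
        assert out.max_violation.iloc[0] == 0.0
        assert out.max_violation.iloc[1] == pytest.approx(0.5, abs=1e-5)
        assert out.frac_violating.iloc[1] == 1.0
        assert (out.sd_distance == 0).all()  # identical models

    def test_pseudoatom_resolves_to_centroid(self, ideal_helix):
        traj = synth.synth_trajectory(ideal_helix, JitterSpec(sigma=0.0, n_frames=2))
        # residue 10 is glycine: HA resolves to the HA2/HA3 centroid
        out = violations(
            traj.ensemble, [DistanceRestraint(10, "HA", 11, "H", 6.0, "sequential")]
        )
        assert np.isfinite(out.mean_distance.iloc[0])

    def test_unresolvable_atom_named(self, ideal_helix):
        traj = synth.synth_trajectory(ideal_helix, JitterSpec(sigma=0.0, n_frames=2))
        with pytest.raises(KeyError, match="HZ9"):
            violations(
                traj.ensemble,
                [DistanceRestraint(5, "HZ9", 8, "H", 5.0, "medium-range")],
            )


class TestUplIO:
    def test_round_trip_preserves_class_counts(self, tmp_path, palustrin_seq, rng):
        # restraint list with the class mixture of a typical short-peptide
        # structure determination: 147 intraresidue / 144 sequential /
        # 130 nonsequential
        restraints = []
        for _ in range(147):
            i = int(rng.integers(2, 29))
            restraints.append(
                DistanceRestraint(i, "HA", i, "HB2", float(rng.uniform(2, 5)),
                                  "intraresidue")
            )
        for _ in range(144):
            i = int(rng.integers(2, 28))
            restraints.append(
                DistanceRestraint(i, "HA", i + 1, "HN", float(rng.uniform(2, 5)),
                                  "sequential")
            )
        for _ in range(130):
            i = int(rng.integers(2, 24))
            off = int(rng.integers(2, 7))
            restraints.append(
                DistanceRestraint(i, "HA", i + off, "HN", float(rng.uniform(2, 6)),
                                  range_class(off))
            )
        path = tmp_path / "restraints.upl"
        write_upl(restraints, path, sequence=palustrin_seq)
        again = read_upl(path)
        assert len(again) == len(restraints)
        counts = count_by_class(again)
        assert counts == {"intraresidue": 147, "sequential": 144,
                          "nonsequential": 130}
        for orig, back in zip(restraints, again):
            assert back.bound == pytest.approx(orig.bound, abs=0.005)
            assert (back.res_i, back.atom_i) == (orig.res_i, orig.atom_i)

    def test_residue_names_written(self, tmp_path, palustrin_seq):
        path = tmp_path / "one.upl"
        write_upl(
            [DistanceRestraint(23, "HB2", 29, "HB3", 4.2, "long-range")],
            path, sequence=palustrin_seq,
        )
        text = path.read_text()
        assert "CYS" in text
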