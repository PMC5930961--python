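"""Secondary-structure track parsing, confidence filtering and net changes."""

import numpy as np
import pytest

from coldbias import (
    SimulationParams,
    net_change_percent,
    paired_ss_sites,
    property_conditioned_ss_change,
    read_ss_track,
    simulate_ss_tracks,
    ss_change_matrix,
)
from coldbias.ortholog_pairing import ProteinAlignment
from coldbias.properties import default_property_table
from coldbias.secstruct import SSSite, SSTrack, read_ss_tracks_tsv, write_ss_tracks_tsv

MW = default_property_table("molecular_weight")


class TestReadSSTrack:
    def test_horizontal_dialect(self, tmp_path):
        path = tmp_path / "x.horiz"
        path.write_text(
            "# PSIPRED HFORMAT\n\nConf: 987\nPred: HHC\n  AA: MKL\n\n"
            "Conf: 60\nPred: CE\n  AA: VW\n"
        )
        track = read_ss_track(path)
        assert track.elements == "HHCCE"
        assert track.confidence == [9, 8, 7, 6, 0]

    def test_vertical_dialect_confidence_rule(self, tmp_path):
        path = tmp_path / "x.ss2"
        path.write_text(
            "# PSIPRED VFORMAT (PSIPRED V4.0)\n\n"
            "   1 M C   0.900 0.050 0.050\n"
            "   2 K H   0.050 0.900 0.050\n"
            "   3 L E   0.334 0.333 0.333\n"
        )
        track = read_ss_track(path)
        assert track.elements == "CHE"
        assert track.confidence == [9, 9, 3]

    def test_full_probability_capped_at_nine(self, tmp_path):
        path = tmp_path / "x.ss2"
        path.write_text("   1 M C   1.000 0.000 0.000\n")
        assert read_ss_track(path).confidence == [9]

    def test_malformed_rejected(self, tmp_path):
        path = tmp_path / "bad.ss2"
        path.write_text("   1 M C 0.9\n")
        with pytest.raises(ValueError):
            read_ss_track(path)

    def test_track_validation(self):
        with pytest.raises(ValueError):
            SSTrack(id="x", elements="HHX", confidence=[9, 9, 9])
        with pytest.raises(ValueError):
            SSTrack(id="x", elements="HH", confidence=[9])

    def test_tsv_roundtrip(self, tmp_path):
        tracks = [SSTrack("t1", "HEC", [9, 5, 0]), SSTrack("t2", "CC", [1, 2])]
        path = tmp_path / "tracks.tsv"
        write_ss_tracks_tsv(tracks, path)
        loaded = read_ss_tracks_tsv(path)
        assert loaded["t1"].elements == "HEC" and loaded["t1"].confidence == [9, 5, 0]
        single = read_ss_track(path)  # single-track reader takes the last row
        assert single.elements == "CC"


class TestPairedSites:
    def _aln(self, a, b):
        return ProteinAlignment("a", "b", a, b, score=0)

    def test_all_high_confidence(self):
        aln = self._aln("MKL", "MKL")
        track = SSTrack("a", "HHH", [9, 9, 9])
        sites, fraction = paired_ss_sites(aln, track, track, min_conf=5)
        assert fraction == 1.0 and len(sites) == 3

    def test_one_side_zero_confidence(self):
        aln = self._aln("MKL", "MKL")
        track_a = SSTrack("a", "HHH", [9, 9, 9])
        track_b = SSTrack("b", "HHH", [0, 0, 0])
        sites, fraction = paired_ss_sites(aln, track_a, track_b, min_conf=5)
        assert fraction == 0.0 and sites == []

    def test_hand_counted_fraction(self):
        aln = self._aln("MKLVWMKLVW", "MKLVWMKLVW")
        conf_a = [9, 9, 9, 9, 9, 9, 0, 0, 0, 9]
        conf_b = [9, 9, 9, 0, 9, 9, 9, 9, 9, 9]
        track_a = SSTrack("a", "H" * 10, conf_a)
        track_b = SSTrack("b", "H" * 10, conf_b)
        _, fraction = paired_ss_sites(aln, track_a, track_b, min_conf=5)
        assert fraction == pytest.approx(0.6)

    def test_threshold_is_strict_by_default(self):
        aln = self._aln("M", "M")
        track = SSTrack("t", "H", [5])
        _, strict = paired_ss_sites(aln, track, track, min_conf=5)
        _, inclusive = paired_ss_sites(aln, track, track, min_conf=5, strictly_greater=False)
        assert strict == 0.0 and inclusive == 1.0

    def test_gap_columns_skipped_and_indices_tracked(self):
        aln = self._aln("M-KL", "MQKL")
        track_a = SSTrack("a", "HEC", [9, 9, 9])
        track_b = SSTrack("b", "HHEC", [9, 9, 9, 9])
        sites, fraction = paired_ss_sites(aln, track_a, track_b, min_conf=5)
        assert fraction == 1.0
        assert [(s.element_a, s.element_b) for s in sites] == [("H", "H"), ("E", "E"), ("C", "C")]

    def test_length_mismatch_rejected(self):
        aln = self._aln("MK", "MK")
        with pytest.raises(ValueError):
            paired_ss_sites(aln, SSTrack("a", "H", [9]), SSTrack("b", "HH", [9, 9]), 5)

    def test_retained_fraction_monotone_in_min_conf(self, rng):
        aln = self._aln("MKLVW" * 4, "MKLVW" * 4)
        conf = [int(c) for c in rng.integers(0, 10, size=20)]
        track = SSTrack("t", "H" * 20, conf)
        fractions = [paired_ss_sites(aln, track, track, min_conf=m)[1] for m in range(10)]
        assert all(f1 >= f2 for f1, f2 in zip(fractions, fractions[1:]))


class TestChangeMatrix:
    def test_counts(self):
        sites = [SSSite("C", "H", "G", "W"), SSSite("C", "H", "G", "W"), SSSite("H", "C", "W", "G")]
        matrix = ss_change_matrix(sites)
        assert matrix.counts[("C", "H")] == 2 and matrix.counts[("H", "C")] == 1
        assert matrix.total_changes() == 3

    def test_net_change_toy_matrix(self):
        sites = [SSSite("C", "H", "G", "W"), SSSite("C", "H", "G", "W"), SSSite("H", "C", "W", "G")]
        net = net_change_percent(ss_change_matrix(sites))
        assert net["C"] == pytest.approx(100 / 3)
        assert net["H"] == pytest.approx(-100 / 3)
        assert net["E"] == 0.0
        assert sum(net.values()) == pytest.approx(0.0)

    def test_symmetric_matrix_zero_net(self):
        sites = [SSSite("C", "H", "G", "W"), SSSite("H", "C", "W", "G")]
        net = net_change_percent(ss_change_matrix(sites))
        assert all(v == 0.0 for v in net.values())

    def test_zero_changes_missing(self):
        assert net_change_percent(ss_change_matrix([SSSite("H", "H", "G", "G")])) is None

    def test_role_swap_transposes(self):
        sites = [SSSite("C", "H", "G", "W"), SSSite("E", "C", "A", "V")]
        matrix = ss_change_matrix(sites)
        transposed = matrix.transposed()
        assert transposed.counts[("H", "C")] == 1 and transposed.counts[("C", "E")] == 1


class TestPropertyConditioned:
    def test_smaller_focal_included_ties_excluded(self):
        sites = [
            SSSite("C", "H", "G", "W"),  # MW(G) < MW(W): included
            SSSite("C", "H", "W", "G"),  # larger on focal side: excluded
            SSSite("C", "H", "G", "G"),  # tie: excluded
        ]
        matrix = property_conditioned_ss_change(sites, MW)
        assert matrix.counts[("C", "H")] == 1 and matrix.total_changes() == 1

    def test_empty_selection_gives_missing_net(self):
        matrix = property_conditioned_ss_change([SSSite("C", "H", "W", "G")], MW)
        assert net_change_percent(matrix) is None


class TestSimulatedTracks:
    def test_identical_proteins_identical_tracks(self, rng):
        params = SimulationParams(coil_gain_bias=3.0, seed=1)
        track_a, track_b = simulate_ss_tracks("MKLVW" * 10, "MKLVW" * 10, params, rng)
        assert track_a.elements == track_b.elements
        assert track_a.confidence == track_b.confidence

    def test_coil_gain_bias_produces_net_coil_gain(self):
        rng = np.random.default_rng(77)
        params = SimulationParams(coil_gain_bias=4.0, seed=1)
        total = {"H": 0.0, "E": 0.0, "C": 0.0}
        for _ in range(60):
            prot_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            prot_b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
            track_a, track_b = simulate_ss_tracks(prot_a, prot_b, params, rng)
            sites = [SSSite(ea, eb, aa, ab) for ea, eb, aa, ab in
                     zip(track_a.elements, track_b.elements, prot_a, prot_b)]
            net = net_change_percent(ss_change_matrix(sites))
            if net is not None:
                assert sum(net.values()) == pytest.approx(0.0, abs=1e-9)
                for e in total:
                    total[e] += net[e]
        assert total["C"] > 0
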