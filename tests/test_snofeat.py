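"""C/D-box motif scanning, length fences, K2P distances, regulation table."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoro_sncrna import snofeat
from fluoro_sncrna.snofeat import (
    C_BOX,
    D_BOX,
    SaturationError,
    SnoRNASeq,
    bounds_from_quantiles,
    dbox_regulation_summary,
    dinucleotide_counts,
    feature_records,
    flag_length_outliers,
    k2p_distance,
    length_outlier_bounds,
    mean_pairwise_k2p,
    normalize_sequence,
    scan_boxes,
)

from conftest import random_rna


def brute_force_positions(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [("acgt", "ACGU"), ("UGAUGA", "UGAUGA"), ("AcGuT", "ACGUU")],
    )
    def test_uppercase_and_t_to_u(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_disallowed_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            normalize_sequence("ACGX")

    def test_n_allowed_only_when_requested(self):
        assert normalize_sequence("ACGN", allow_n=True) == "ACGN"
        with pytest.raises(ValueError):
            normalize_sequence("ACGN")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_sequence("")


class TestScanBoxes:
    def test_single_dbox_terminal_5p(self):
        (box,) = scan_boxes("CUGA")
        assert (box.box_type, box.start, box.end, box.position_class) == ("D", 0, 4, "terminal_5p")

    def test_positional_classes_on_constructed_sequence(self):
        seq = C_BOX + "A" * 20 + D_BOX + "A" * 20 + D_BOX  # length 54
        boxes = scan_boxes(seq)
        by_pos = {(b.box_type, b.start): b for b in boxes}
        assert set(by_pos) == {("C", 0), ("D", 26), ("D", 50)}
        assert by_pos[("C", 0)].position_class == "terminal_5p"
        assert by_pos[("D", 26)].position_class == "internal"
        assert by_pos[("D", 50)].position_class == "terminal_3p"

    def test_adjacent_dboxes_both_reported(self):
        boxes = scan_boxes("CUGACUGA")
        assert [(b.start, b.end) for b in boxes] == [(0, 4), (4, 8)]

    def test_5p_precedence_when_both_windows_apply(self):
        # short sequence: both terminal windows cover everything
        (box,) = scan_boxes("AAACUGAAA", terminal_window=15)
        assert box.position_class == "terminal_5p"

    def test_annotation_matches_sequence(self, rng):
        for _ in range(50):
            seq = random_rna(rng, int(rng.integers(10, 200)))
            for b in scan_boxes(seq):
                assert seq[b.start : b.end] == b.motif

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            seq = random_rna(rng, int(rng.integers(6, 150)))
            boxes = scan_boxes(seq)
            for box_type, motif in (("C", C_BOX), ("D", D_BOX)):
                found = sorted(b.start for b in boxes if b.box_type == box_type)
                assert found == brute_force_positions(seq, motif)


class TestDinucleotides:
    @pytest.mark.parametrize(
        "seq,expected",
        [("UGUG", {"UG": 2, "CG": 0}), ("CGCG", {"UG": 0, "CG": 2}), ("AAAA", {"UG": 0, "CG": 0})],
    )
    def test_overlapping_window_counts(self, seq, expected):
        assert dinucleotide_counts(seq) == expected

    def test_short_sequence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dinucleotide_counts("A") == {"UG": 0, "CG": 0}


class TestLengthBounds:
    def test_degenerate_equal_lengths(self):
        b = length_outlier_bounds([80, 80, 80, 80])
        assert b.q25 == b.q75 == b.lower == b.upper == 80.0
        assert b.iqr == 0.0

    def test_seven_value_worked_example(self):
        b = length_outlier_bounds([48, 70, 75, 80, 88, 90, 120])
        assert b.q25 == pytest.approx(72.5)
        assert b.q75 == pytest.approx(89.0)
        assert b.iqr == pytest.approx(16.5)
        assert b.lower == pytest.approx(47.75)
        assert b.upper == pytest.approx(113.75)

    def test_fence_rule_from_given_quartiles(self):
        b = bounds_from_quantiles(70.995, 87.745)
        assert b.lower == pytest.approx(45.87, abs=1e-9)
        assert b.upper == pytest.approx(112.87, abs=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            length_outlier_bounds([1, 2, 3])

    @given(
        lengths=st.lists(st.integers(10, 500), min_size=4, max_size=40),
        c=st.integers(-50, 50),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_translation_equivariance(self, lengths, c):
        b0 = length_outlier_bounds(lengths)
        b1 = length_outlier_bounds([L + c for L in lengths])
        for attr in ("q25", "q75", "lower", "upper"):
            assert getattr(b1, attr) == pytest.approx(getattr(b0, attr) + c)
        assert b1.iqr == pytest.approx(b0.iqr)

    @given(lengths=st.lists(st.integers(10, 500), min_size=4, max_size=40), k=st.integers(2, 5))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_scale_equivariance(self, lengths, k):
        b0 = length_outlier_bounds(lengths)
        b1 = length_outlier_bounds([L * k for L in lengths])
        for attr in ("q25", "q75", "iqr", "lower", "upper"):
            assert getattr(b1, attr) == pytest.approx(getattr(b0, attr) * k)


class TestFlagOutliers:
    def lengths_to_seqs(self, lengths):
        return [SnoRNASeq(id=f"s{i}", sequence="A" * L) for i, L in enumerate(lengths)]

    def test_empty_set(self):
        assert flag_length_outliers([], threshold=100.0) == []

    def test_threshold_usage_is_inclusive(self):
        seqs = self.lengths_to_seqs([48, 90, 114, 237])
        out = flag_length_outliers(seqs, threshold=112.87)
        assert [s.length for s in out] == [114, 237]

    def test_both_sides_returns_short_sequences_too(self):
        seqs = self.lengths_to_seqs([30, 48, 90, 114, 237])
        b = bounds_from_quantiles(70.995, 87.745)  # fences 45.87 / 112.87
        out = flag_length_outliers(seqs, bounds=b, side="both_sides")
        assert [s.length for s in out] == [30, 114, 237]
        # lengths >= 48 produce no lower-side outliers under these fences
        out_hi = flag_length_outliers(seqs[1:], bounds=b, side="both_sides")
        assert [s.length for s in out_hi] == [114, 237]


class TestK2P:
    def test_identical_sequences(self):
        r = k2p_distance("ACGUACGUAC", "ACGUACGUAC")
        assert r.p_transitions == 0 and r.q_transversions == 0 and r.distance == 0

    def test_one_transition_one_transversion_in_ten(self):
        a = "AAAAAAAAGC"
        b = "AAAAAAAAAA"  # pos 8: G->A transition; pos 9: C->A transversion
        r = k2p_distance(a, b, aligner="none")
        assert r.p_transitions == pytest.approx(0.1)
        assert r.q_transversions == pytest.approx(0.1)
        expected = -0.5 * math.log(1 - 0.3) - 0.25 * math.log(1 - 0.2)
        assert r.distance == pytest.approx(expected, abs=1e-12)
        assert r.distance == pytest.approx(0.234123, abs=1e-5)

    def test_saturation_raises(self):
        # 5 transitions in 10 sites: P=0.5, Q=0 -> 1-2P-Q = 0
        a = "AAAAAGGGGG"
        b = "AAAAAAAAAA"
        with pytest.raises(SaturationError):
            k2p_distance(a, b, aligner="none")

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_rna(rng, 60), random_rna(rng, 55)
            try:
                ra, rb = k2p_distance(a, b), k2p_distance(b, a)
            except SaturationError:
                continue
            assert ra.distance == pytest.approx(rb.distance)

    def test_exceeds_raw_mismatch_proportion_at_small_divergence(self, rng):
        # Jukes-Cantor-style expansion: the corrected distance is above the
        # observed mismatch fraction whenever P + Q > 0
        base = random_rna(rng, 100)
        mutated = list(base)
        for i in rng.choice(100, size=8, replace=False):
            mutated[i] = {"A": "G", "G": "A", "C": "U", "U": "C"}[mutated[i]]
        r = k2p_distance(base, "".join(mutated), aligner="none")
        assert r.distance > r.p_transitions + r.q_transversions

    def test_unequal_lengths_are_aligned(self):
        a = "ACGUACGUACGUACGUACGU"
        r = k2p_distance(a, a[2:])  # pure prefix deletion: gap columns excluded
        assert r.distance == 0.0

    def test_mean_pairwise_requires_two(self):
        with pytest.raises(ValueError):
            mean_pairwise_k2p([SnoRNASeq(id="a", sequence="ACGU")])

    def test_mean_pairwise_identical_pair_is_zero(self):
        seqs = [SnoRNASeq(id=i, sequence="ACGUACGUAC") for i in "ab"]
        assert mean_pairwise_k2p(seqs).mean == 0.0

    def test_mean_pairwise_permutation_invariant(self, rng):
        base = random_rna(rng, 80)
        seqs = []
        for i in range(4):
            m = list(base)
            for j in rng.choice(80, size=4, replace=False):
                m[j] = {"A": "G", "G": "A", "C": "U", "U": "C"}[m[j]]
            seqs.append(SnoRNASeq(id=f"s{i}", sequence="".join(m)))
        fwd = mean_pairwise_k2p(seqs)
        rev = mean_pairwise_k2p(list(reversed(seqs)))
        assert fwd.mean == pytest.approx(rev.mean)
        assert fwd.n_pairs_used == rev.n_pairs_used == 6


class TestDBoxRegulation:
    def record(self, i, d, direction, outlier=True):
        return snofeat.FeatureRecord(
            id=f"s{i}", length=150 if outlier else 80, c_box_count=1, d_box_count=d,
            ug_count=0, cg_count=0, is_length_outlier=outlier,
            regulation={"8mg": direction},
        )

    def test_enumerated_contingency(self):
        recs = [self.record(0, 3, "down"), self.record(1, 2, "down"),
                self.record(2, 1, "up"), self.record(3, 0, "up")]
        s = dbox_regulation_summary(recs, dose="8mg")
        assert s.frac_down_multi == 1.0 and s.frac_down_single == 0.0
        assert (s.n_multi_down, s.n_multi_other, s.n_single_down, s.n_single_other) == (2, 0, 0, 2)

    def test_non_outliers_excluded(self):
        recs = [self.record(0, 3, "down"), self.record(1, 3, "up", outlier=False)]
        s = dbox_regulation_summary(recs, dose="8mg")
        assert s.n_multi_down == 1 and s.n_multi_other == 0

    def test_missing_regulation_lists_ids(self):
        bad = snofeat.FeatureRecord(
            id="orphan", length=150, c_box_count=1, d_box_count=2,
            ug_count=0, cg_count=0, is_length_outlier=True, regulation=None,
        )
        with pytest.raises(ValueError, match="orphan"):
            dbox_regulation_summary([bad], dose="8mg")

    def test_empty_outlier_set_warns(self):
        recs = [self.record(0, 2, "down", outlier=False)]
        with pytest.warns(UserWarning):
            s = dbox_regulation_summary(recs, dose="8mg")
        assert s.n_multi_down == 0 and math.isnan(s.frac_down_multi)


def test_feature_records_report_all_features(rng):
    seqs = [
        SnoRNASeq(id="a", sequence=C_BOX + "A" * 50 + D_BOX),
        SnoRNASeq(id="b", sequence="A" * 60),
        SnoRNASeq(id="c", sequence="UGUGUG" + "A" * 54),
        SnoRNASeq(id="d", sequence="A" * 200),
    ]
    recs = feature_records(seqs, bounds=bounds_from_quantiles(60, 80))
    by_id = {r.id: r for r in recs}
    assert by_id["a"].c_box_count == 1 and by_id["a"].d_box_count == 1
    assert by_id["b"].c_box_count == by_id["b"].d_box_count == 0
    assert by_id["c"].ug_count == 3
    assert by_id["d"].is_length_outlier and not by_id["a"].is_length_outlier
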