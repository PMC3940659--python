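from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_sequence
from idrscape.cohort_stats import (
    DisorderAnnotation,
    ProteinSummary,
    build_protein_summary,
    chou_fasman_baseline,
    classify_protein,
    composition_profile,
    disorder_fraction,
    ss_preference,
    summarize_class,
)
from idrscape.region_algebra import Interval, region_set
from idrscape.seq_io import ProteinRecord


def make_summary(pid, disorder_pct, ar_count=0):
    return ProteinSummary(
        protein_id=pid, length=100, disorder_pct=disorder_pct,
        ar_pct=0.0, lcr_pct=0.0, ar_count=ar_count, lcr_count=0,
        overlap_count=0, class_label=classify_protein(disorder_pct),
        n_terminal_ars=0, c_terminal_ars=0,
    )


class TestDisorderFraction:
    def test_full_coverage_is_100(self):
        ann = DisorderAnnotation("p", (Interval(1, 50),))
        assert disorder_fraction(ann, 50) == 100.0

    def test_no_intervals_is_zero(self):
        assert disorder_fraction(DisorderAnnotation("p", ()), 50) == 0.0

    def test_matches_boolean_mask_oracle(self, rng):
        from conftest import random_intervals

        for _ in range(200):
            length = int(rng.integers(20, 300))
            ivs = random_intervals(rng, int(rng.integers(0, 6)), length)
            ann = DisorderAnnotation("p", tuple(Interval(*iv) for iv in ivs))
            mask = np.zeros(length + 1, dtype=bool)
            for s, e in ivs:
                mask[s : e + 1] = True
            assert disorder_fraction(ann, length) == pytest.approx(
                100.0 * mask.sum() / length
            )

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            disorder_fraction(DisorderAnnotation("p", ()), 0)


class TestClassify:
    @pytest.mark.parametrize(
        "pct,label",
        [(0, "PDP"), (30, "PDP"), (30.5, "MDP"), (50, "MDP"), (70, "MDP"),
         (70.5, "LDP"), (100, "LDP")],
    )
    def test_boundaries(self, pct, label):
        assert classify_protein(pct) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_protein(101)

    @given(pct=st.floats(0, 100, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_of_unit_interval(self, pct):
        assert classify_protein(pct) in ("PDP", "MDP", "LDP")


class TestClassSummary:
    def test_amyloidogenic_percentages(self):
        rows = [make_summary(f"p{i}", 10.0, ar_count=1) for i in range(99)]
        rows += [make_summary(f"q{i}", 10.0, ar_count=0) for i in range(8)]
        out = {r.class_label: r for r in summarize_class(rows)}
        assert out["PDP"].total_proteins == 107
        assert out["PDP"].amyloidogenic_count == 99
        assert out["PDP"].amyloidogenic_pct == pytest.approx(92.52, abs=0.005)

    def test_all_amyloidogenic_is_100(self):
        rows = [make_summary(f"p{i}", 90.0, ar_count=2) for i in range(8)]
        out = {r.class_label: r for r in summarize_class(rows)}
        assert out["LDP"].amyloidogenic_pct == 100.0

    def test_single_protein_without_ar(self):
        out = summarize_class([make_summary("p", 50.0)])
        labels = [r.class_label for r in out]
        assert labels == ["MDP", "Total"]
        assert out[0].amyloidogenic_pct == 0.0

    def test_total_row_equals_sum_of_classes(self):
        rows = (
            [make_summary(f"a{i}", 10, i % 2) for i in range(7)]
            + [make_summary(f"b{i}", 50, 1) for i in range(5)]
            + [make_summary(f"c{i}", 90, 0) for i in range(3)]
        )
        out = summarize_class(rows)
        total = out[-1]
        assert total.class_label == "Total"
        parts = out[:-1]
        assert total.total_proteins == sum(r.total_proteins for r in parts)
        assert total.ar_count == sum(r.ar_count for r in parts)
        assert total.amyloidogenic_count == sum(r.amyloidogenic_count for r in parts)

    def test_empty_input_gives_empty_output(self):
        assert summarize_class([]) == []


class TestComposition:
    def test_single_region_homopolymer(self):
        rec = ProteinRecord("p", "MKVAAAAAWL")
        regions = {"p": region_set("p", "LCR", [(4, 8)])}
        prof = composition_profile([rec], regions, context="LCR")
        assert prof.freqs["A"] == 100.0
        assert sum(prof.freqs.values()) == pytest.approx(100.0)

    def test_whole_protein_letter_counts(self):
        prof = composition_profile([ProteinRecord("p", "KLVFFA")])
        for aa, expected in (("K", 100 / 6), ("F", 200 / 6)):
            assert prof.freqs[aa] == pytest.approx(expected)

    def test_permutation_invariance_and_normalization(self, rng):
        recs = [ProteinRecord(f"p{i}", random_sequence(rng, 50)) for i in range(6)]
        a = composition_profile(recs)
        b = composition_profile(list(reversed(recs)))
        assert a.freqs == b.freqs
        assert sum(a.freqs.values()) == pytest.approx(100.0)

    def test_empty_context_rejected(self):
        with pytest.raises(ValueError):
            composition_profile([ProteinRecord("p", "MKV")], {}, context="AR")


class TestSsPreference:
    def test_all_helix(self):
        pref = ss_preference("H" * 9, 9, region_set("p", "AR", [(2, 5)]))
        assert (pref.helix_pct, pref.sheet_pct, pref.coil_pct) == (100.0, 0.0, 0.0)

    def test_region_slice(self):
        pref = ss_preference("HHHEEECCC", 9, region_set("p", "AR", [(4, 6)]))
        assert (pref.helix_pct, pref.sheet_pct, pref.coil_pct) == (0.0, 100.0, 0.0)

    def test_matches_tally_oracle(self, rng):
        from conftest import random_intervals

        for _ in range(100):
            length = int(rng.integers(10, 120))
            ann = "".join(rng.choice(list("HEC"), length))
            ivs = random_intervals(rng, int(rng.integers(1, 4)), length)
            rs = region_set("p", "AR", ivs)
            mask = np.zeros(length + 1, dtype=bool)
            for s, e in ivs:
                mask[s : e + 1] = True
            in_ctx = [ann[i - 1] for i in range(1, length + 1) if mask[i]]
            tally = Counter(in_ctx)
            pref = ss_preference(ann, length, rs)
            assert pref.helix_pct == pytest.approx(100 * tally["H"] / len(in_ctx))
            assert pref.sheet_pct == pytest.approx(100 * tally["E"] / len(in_ctx))

    def test_per_region_majority_mode(self):
        rs = region_set("p", "AR", [(1, 3), (4, 9)])
        pref = ss_preference("HHHCCCCCC", 9, rs, per_region=True)
        assert pref.helix_pct == 50.0
        assert pref.coil_pct == 50.0

    def test_length_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ss_preference("HEC", 4)
        with pytest.raises(ValueError, match="labels"):
            ss_preference("HEX", 3)


class TestChouFasmanBaseline:
    def test_poly_alanine_is_helix(self):
        assert chou_fasman_baseline(ProteinRecord("p", "A" * 10)) == "H" * 10

    def test_poly_glycine_is_coil(self):
        assert chou_fasman_baseline(ProteinRecord("p", "G" * 10)) == "C" * 10

    def test_poly_valine_is_sheet(self):
        assert chou_fasman_baseline(ProteinRecord("p", "V" * 4)) == "E" * 4

    def test_length_preserved(self, rng):
        rec = ProteinRecord("p", random_sequence(rng, 77))
        assert len(chou_fasman_baseline(rec)) == 77


def test_build_protein_summary_integrates_metrics():
    rec = ProteinRecord("DP00069", "M" * 116)
    ars = region_set("DP00069", "AR", [(101, 116)])
    lcrs = region_set("DP00069", "LCR", [(3, 24), (97, 112)])
    ann = DisorderAnnotation("DP00069", (Interval(1, 95),))
    s = build_protein_summary(rec, ars, lcrs, ann)
    assert s.class_label == "LDP"
    assert s.ar_count == 1 and s.lcr_count == 2
    assert s.overlap_count == 1
    assert (s.n_terminal_ars, s.c_terminal_ars) == (0, 1)
    assert s.amyloidogenic
    assert s.ar_pct == pytest.approx(100 * 16 / 116)
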