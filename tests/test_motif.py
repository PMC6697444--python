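"""Element patterns, matching, counting, ratios, and the PFM summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufselect import (BUILTIN_PATTERNS, ElementPattern, InputError,
                       PatternCountTable, UndefinedRatioError, build_pfm,
                       compact_extended_ratio, count_patterns, match_pattern,
                       round_sig)
from conftest import naive_match, random_reads

COMPACT = BUILTIN_PATTERNS["compact"]
EXTENDED = BUILTIN_PATTERNS["extended"]

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestElementPattern:
    def test_builtin_patterns_have_expected_geometry(self):
        # compact: one degenerate base before the terminal AU (U at +7);
        # extended: two (U at +8)
        assert COMPACT.terminal_AU_position == 7
        assert EXTENDED.terminal_AU_position == 8
        assert BUILTIN_PATTERNS["compact_G4"].base4 == "G"
        assert BUILTIN_PATTERNS["extended_A4"].base4 == "A"
        assert COMPACT.base4 == "R"

    @pytest.mark.parametrize("bad", [
        "TGTRNAT",      # missing the -1 C
        "CTGTRNNNAT",   # three degenerate centers
        "CTGTRNAG",     # no terminal AU
        "CTGXRNAT",     # invalid character
    ])
    def test_invalid_patterns_rejected(self, bad):
        with pytest.raises(InputError):
            ElementPattern("bad", bad, "compact")

    def test_dot_and_u_accepted_in_pattern_text(self):
        p = ElementPattern("x", "CUGUA.AU", "compact")
        assert p.pattern == "CTGTANAT"


class TestMatchPattern:
    def test_crystallized_element_matches_compact(self):
        # the 8-nt element from the ternary-complex structure, 5'-CUGUGAAU-3'
        assert match_pattern("CTGTGAAT", COMPACT)
        assert match_pattern("CUGUGAAU", COMPACT)  # RNA alphabet

    def test_no_upstream_c_fails_extended(self):
        # gld-1 FBEa context has an A immediately 5' of UGU
        assert not match_pattern("CATGTGCCATA", EXTENDED)
        assert match_pattern("CCTGTGCCATA", EXTENDED)

    def test_read_without_tgt_matches_nothing(self, all_builtin_patterns):
        read = "ACACACACACACACACAC"
        assert not any(match_pattern(read, p) for p in all_builtin_patterns)

    def test_read_can_match_both_classes(self):
        read = "CTGTGAATCTGTGAAAT"
        assert match_pattern(read, COMPACT)      # offset 0
        assert match_pattern(read, EXTENDED)     # offset 8
        assert naive_match(read, COMPACT.pattern)
        assert naive_match(read, EXTENDED.pattern)

    def test_non_nucleotide_read_rejected(self):
        with pytest.raises(InputError):
            match_pattern("CTGTXAAT", COMPACT)

    @given(read=dna)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matcher_equals_naive_oracle(self, read):
        for p in BUILTIN_PATTERNS.values():
            assert match_pattern(read, p) == naive_match(read, p.pattern)


class TestCountPatterns:
    def test_constructed_counts(self):
        matching = ["AA" + "CTGTGAAT" + "CC"] * 3
        nonmatching = ["ACACACACACAC"] * 7
        table = count_patterns(matching + nonmatching,
                               [BUILTIN_PATTERNS["compact_G4"],
                                BUILTIN_PATTERNS["extended_G4"]], "ds")
        assert table.count("ds", "compact_G4") == 3
        assert table.count("ds", "extended_G4") == 0

    def test_counting_is_pure(self, all_builtin_patterns):
        reads = random_reads(500, 30, seed=7)
        t1 = count_patterns(reads, all_builtin_patterns, "ds")
        t2 = count_patterns(reads, all_builtin_patterns, "ds")
        assert t1.table.equals(t2.table)

    def test_read_level_semantics(self):
        # a read with two compact occurrences still counts once
        reads = ["CTGTGAAT" + "CTGTGAAT"]
        t = count_patterns(reads, [BUILTIN_PATTERNS["compact_G4"]], "ds")
        assert t.count("ds", "compact_G4") == 1
        t_occ = count_patterns(reads, [BUILTIN_PATTERNS["compact_G4"]], "ds",
                               occurrences=True)
        assert t_occ.count("ds", "compact_G4") == 2

    def test_dedup_collapses_identical_reads(self):
        reads = ["CTGTGAAT"] * 5 + ["CTGTAAAT"] * 2
        t = count_patterns(reads, [COMPACT], "ds", dedup=True)
        assert t.count("ds", "compact") == 2

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            count_patterns([], [COMPACT], "ds")
        with pytest.raises(InputError):
            count_patterns(["ACGT"], [], "ds")

    def test_alphabet_invariance(self, all_builtin_patterns):
        reads = random_reads(300, 30, seed=11)
        rna = [r.replace("T", "U") for r in reads]
        t_dna = count_patterns(reads, all_builtin_patterns, "ds")
        t_rna = count_patterns(rna, all_builtin_patterns, "ds")
        assert t_dna.table.equals(t_rna.table)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_subset_monotonicity(self, seed, all_builtin_patterns):
        reads = random_reads(200, 30, seed=seed)
        t_half = count_patterns(reads[:100], all_builtin_patterns, "ds")
        t_full = count_patterns(reads, all_builtin_patterns, "ds")
        for p in all_builtin_patterns:
            assert t_full.count("ds", p.name) >= t_half.count("ds", p.name)


class TestRatio:
    def test_equal_counts_give_unity(self):
        t = PatternCountTable.from_counts(
            {("d", "compact_A4"): 50, ("d", "extended_A4"): 50})
        assert compact_extended_ratio(t, "d", "A") == 1.0

    def test_zero_extended_count_is_undefined(self):
        t = PatternCountTable.from_counts(
            {("d", "compact_A4"): 5, ("d", "extended_A4"): 0})
        with pytest.raises(UndefinedRatioError):
            compact_extended_ratio(t, "d", "A")

    def test_missing_counts_raise(self):
        t = PatternCountTable.from_counts({("d", "compact_A4"): 5})
        with pytest.raises(KeyError):
            compact_extended_ratio(t, "d", "A")

    def test_report_table_shows_dot_for_undefined(self):
        t = PatternCountTable.from_counts(
            {("d", "compact_A4"): 5, ("d", "extended_A4"): 0})
        frame = t.to_frame()
        assert set(frame["ratio_compact_extended"]) == {"."}


class TestBuildPfm:
    def test_single_read_gives_one_hot_columns(self):
        pfm = build_pfm(["AC" + "CTGTGAAT" + "GG"], COMPACT)
        assert pfm.n_sites == 1
        assert np.allclose(pfm.probs.to_numpy().max(axis=1), 1.0)
        assert np.allclose(pfm.information_content, 2.0)
        assert pfm.positions == [-2, -1] + list(range(1, 10))

    def test_half_split_position_has_one_bit(self):
        r1 = "AC" + "CTGTGAAT" + "GG"
        r2 = "AC" + "CTGTGCAT" + "GG"  # differs only at +5 (A vs C)
        pfm = build_pfm([r1, r2], COMPACT)
        by_pos = dict(zip(pfm.positions, pfm.information_content))
        assert by_pos[5] == pytest.approx(1.0)
        for pos, ic in by_pos.items():
            if pos != 5:
                assert ic == pytest.approx(2.0)

    def test_columns_sum_to_one(self):
        reads = [r for r in random_reads(2000, 40, seed=3)
                 if COMPACT.regex.search(r)]
        if not reads:
            pytest.skip("no chance matches at this seed")
        pfm = build_pfm(reads, COMPACT)
        assert np.allclose(pfm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pfm.information_content >= -1e-12)
        assert np.all(pfm.information_content <= 2 + 1e-12)

    def test_unanchorable_reads_rejected(self):
        with pytest.raises(InputError):
            build_pfm(["ACACACAC"], COMPACT)
        # match present but window would run off the read
        with pytest.raises(InputError):
            build_pfm(["CTGTGAAT"], COMPACT)


def test_round_sig_matches_report_precision():
    assert round_sig(0.2079, 2) == 0.21
    assert round_sig(2.795, 2) == 2.8
    assert round_sig(21.03, 2) == 21
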