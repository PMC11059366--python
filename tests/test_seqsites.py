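"""Seed-site discovery: normalization, patterns, scanning, overlaps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from utrscreen import (
    AlphabetError,
    MiRNA,
    UTRSequence,
    count_sites,
    find_seed_sites,
    gc_content,
    normalize_sequence,
    pairwise_site_overlap,
    reverse_complement,
    site_patterns,
)

from oracles import random_rna, scan_oracle

rna = st.text(alphabet="ACGU", min_size=1, max_size=60)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("acgt", "ACGU"),
            ("CUUUUUGCGGUCUGGGCUUGC", "CUUUUUGCGGUCUGGGCUUGC"),
            ("AcGuT", "ACGUU"),
        ],
    )
    def test_valid(self, raw, expected):
        assert normalize_sequence(raw) == expected

    def test_invalid_character_names_position(self):
        with pytest.raises(AlphabetError) as err:
            normalize_sequence("ACGN")
        assert err.value.position == 4

    def test_empty(self):
        with pytest.raises(ValueError):
            normalize_sequence("")


class TestReverseComplement:
    def test_hand_example(self):
        assert reverse_complement("UUUUUG") == "CAAAAA"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            reverse_complement("")

    @given(rna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    @given(rna)
    def test_gc_count_preserved(self, seq):
        assert gc_content(seq) == gc_content(reverse_complement(seq))


class TestSitePatterns:
    def test_mir129_patterns(self, mir129):
        assert site_patterns(mir129) == {
            "6mer": "CAAAAA",
            "7mer-m8": "GCAAAAA",
            "7mer-A1": "CAAAAAA",
            "8mer": "GCAAAAAA",
        }

    def test_homopolymer(self):
        assert site_patterns(MiRNA("m", "AAAAAAAA"))["6mer"] == "UUUUUU"

    @given(st.text(alphabet="ACGU", min_size=8, max_size=25))
    def test_8mer_always_ends_in_a(self, seq):
        assert site_patterns(MiRNA("m", seq))["8mer"].endswith("A")

    def test_too_short(self):
        with pytest.raises(ValueError):
            MiRNA("m", "ACGUACG")


class TestFindSeedSites:
    @pytest.mark.parametrize(
        "fragment, expected",
        [
            ("AUGCAAAAAAGG", [("8mer", 3, 10)]),
            ("GGGGGGGG", []),
            ("CCAAAAAC", [("6mer", 2, 7)]),
            ("GCAAAAAG", [("7mer-m8", 1, 7)]),
            ("CCAAAAAA", [("7mer-A1", 2, 8)]),
        ],
    )
    def test_worked_examples(self, mir129, fragment, expected):
        frag = UTRSequence("g", "f1", fragment)
        found = [(s.site_type, s.start, s.end) for s in find_seed_sites(frag, mir129)]
        assert found == expected

    def test_target_seq_matches_fragment(self, mir129):
        frag = UTRSequence("g", "f1", "AUGCAAAAAAGG")
        (site,) = find_seed_sites(frag, mir129)
        assert site.target_seq == frag.sequence[site.start - 1 : site.end]

    def test_matches_exhaustive_oracle(self, rng):
        """Scanner == per-offset pattern comparison on random inputs."""
        for _ in range(150):
            frag_seq = random_rna(rng, int(rng.integers(20, 501)))
            mir_seq = random_rna(rng, int(rng.integers(18, 24)))
            frag = UTRSequence("g", "f", frag_seq)
            mir = MiRNA("m", mir_seq)
            found = [(s.site_type, s.start, s.end)
                     for s in find_seed_sites(frag, mir)]
            assert found == scan_oracle(frag_seq, mir_seq)

    def test_type_maximality(self, rng):
        """No reported site could be upgraded to a stronger class."""
        mir = MiRNA("m", random_rna(rng, 22))
        pats = site_patterns(mir)
        for _ in range(50):
            seq = random_rna(rng, 300)
            frag = UTRSequence("g", "f", seq)
            for s in find_seed_sites(frag, mir):
                if s.site_type == "6mer":
                    core0 = s.start - 1  # 0-based core start
                    assert seq[max(0, core0 - 1): core0 + 7] != pats["8mer"]
                    assert not (core0 >= 1 and
                                seq[core0 - 1: core0 + 6] == pats["7mer-m8"])
                    assert seq[core0: core0 + 7] != pats["7mer-A1"]
                elif s.site_type in ("7mer-m8", "7mer-A1"):
                    core0 = s.start if s.site_type == "7mer-m8" else s.start - 1
                    assert seq[core0 - 1: core0 + 7] != pats["8mer"]

    def test_overlapping_cores_each_reported(self):
        mir = MiRNA("m", "AUUUUUUUUU")  # seed UUUUUU -> core AAAAAA
        frag = UTRSequence("g", "f", "CCAAAAAAACC")
        found = find_seed_sites(frag, mir)
        assert len(found) >= 2


class TestCountSites:
    def test_single(self, mir129):
        assert count_sites(UTRSequence("g", "f", "AUGCAAAAAAGG"), mir129) == 1

    def test_none(self, mir129):
        assert count_sites(UTRSequence("g", "f", "GGGGGGGG"), mir129) == 0

    def test_two_disjoint_planted_cores(self, mir129):
        seq = "UGGCAAAAAAGG" + "CGCG" + "GGCAAAAAAGU"
        frag = UTRSequence("g", "f", seq)
        assert count_sites(frag, mir129) == len(scan_oracle(seq, mir129.sequence)) == 2


class TestGcContent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("UUUUUG", 16.7), ("GCGC", 100.0), ("AUAU", 0.0), ("GCAU", 50.0)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestPairwiseSiteOverlap:
    def test_pair_intersection(self):
        out = pairwise_site_overlap({"m1": {"a", "b"}, "m2": {"b", "c"}})
        assert out[("m1", "m2")] == 1

    def test_disjoint(self):
        out = pairwise_site_overlap({"m1": {"a"}, "m2": {"b"}, "m3": {"c"}})
        assert all(v == 0 for v in out.values())

    def test_triple(self):
        out = pairwise_site_overlap({"m1": {"a"}, "m2": {"a"}, "m3": {"a"}})
        assert out[("m1", "m2", "m3")] == 1
        assert out[("m1", "m2")] == 1
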