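import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palinscan.palindrome_scan import (ControlWindow, PalindromeHit,
                                       ScanConfig, enumerate_palindromes,
                                       filter_hits, is_palindrome,
                                       sample_control_windows, scan_chain,
                                       unique_sequences)
from palinscan.structure_io import ChainSequence

from .oracles import probe_target_scan

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_chain(seq, complete=None, pdb_id="TEST", chain_id="A"):
    return ChainSequence(
        chain_id=chain_id, sequence=seq,
        residue_index=[(i + 1, "") for i in range(len(seq))],
        complete_mask=list(complete) if complete is not None
        else [True] * len(seq),
        pdb_id=pdb_id)


class TestIsPalindrome:
    @pytest.mark.parametrize("seq,expected", [
        ("RALAR", True),        # odd-length palindrome
        ("VGFFGV", True),       # even-length palindrome
        ("GDNPRPNDG", True),    # 9-mer palindrome
        ("AAIAC", False),
        ("AAAAA", True),        # CARP is palindromic; excluded downstream
        ("AXA", False),         # 'X' never matches itself
        ("QKAKQ", True),
    ])
    def test_examples(self, seq, expected):
        assert is_palindrome(seq) is expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            is_palindrome("")


class TestEnumerate:
    def test_overlapping_pentapalindromes(self):
        hits = enumerate_palindromes(make_chain("FAFAFA"))
        assert [(h.sequence, h.start_index) for h in hits] == [
            ("FAFAF", 0), ("AFAFA", 1)]

    def test_cocentred_nest(self):
        # 5-mer, 7-mer and 9-mer share a centre in this chain
        hits = enumerate_palindromes(make_chain("AEQKAKQEA"))
        assert {(h.sequence, h.start_index) for h in hits} == {
            ("AEQKAKQEA", 0), ("EQKAKQE", 1), ("QKAKQ", 2)}

    def test_short_chain_empty(self):
        assert enumerate_palindromes(make_chain("AAAA")) == []

    def test_author_positions(self):
        hits = enumerate_palindromes(make_chain("GGRALARGG"))
        hit = next(h for h in hits if h.sequence == "RALAR")
        assert hit.location == "3-7"

    def test_maximal_only_option(self):
        cfg = ScanConfig(maximal_only=True)
        hits = enumerate_palindromes(make_chain("AEQKAKQEA"), cfg)
        assert [(h.sequence, h.start_index) for h in hits] == [("AEQKAKQEA", 0)]


class TestFilters:
    def test_carp_removed(self):
        chain = make_chain("GGAAAAAGG")
        kept = scan_chain(chain)
        assert all(len(set(h.sequence)) > 1 for h in kept)

    def test_carp_logged(self):
        chain = make_chain("GGAAAAAGG")
        log = []
        scan_chain(chain, exclusion_log=log)
        assert any(reason == "CARP" for _, reason in log)

    def test_incomplete_residue_removes_window(self):
        seq = "GGDNYNDGG"
        complete = [True] * 9
        complete[4] = False  # the central Y lacks atoms
        kept = scan_chain(make_chain(seq, complete=complete))
        assert all("DNYND" != h.sequence for h in kept)
        kept_ok = scan_chain(make_chain(seq))
        assert any(h.sequence == "DNYND" for h in kept_ok)

    def test_positional_duplicates_collapse(self):
        chain = make_chain("GGQKAKQGG")
        hits = enumerate_palindromes(chain)
        doubled = hits + hits
        assert filter_hits(doubled, chain) == filter_hits(hits, chain)

    def test_out_of_range_hit_is_error(self):
        chain = make_chain("GGQKAKQGG")
        bogus = PalindromeHit("TEST", "A", 7, "QKAKQ")
        with pytest.raises(ValueError, match="outside"):
            filter_hits([bogus], chain)


class TestOracleEquivalence:
    def test_matches_probe_target_search(self):
        """Window enumeration + filters equal a literal sliding probe/target
        search on seeded random sequences (lengths up to 60)."""
        rng = np.random.default_rng(1234)
        n_mismatch = 0
        for _ in range(1000):
            length = int(rng.integers(5, 61))
            seq = "".join(rng.choice(list(AA + "X"), size=length,
                                     p=[0.049] * 20 + [0.02]))
            chain = make_chain(seq)
            mine = {(h.start_index, h.length) for h in scan_chain(chain)}
            oracle = probe_target_scan(seq)
            if mine != oracle:
                n_mismatch += 1
        assert n_mismatch == 0


class TestProperties:
    @given(st.text(alphabet=AA, min_size=5, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_every_hit_is_palindromic_non_carp(self, seq):
        for hit in scan_chain(make_chain(seq)):
            assert hit.sequence == hit.sequence[::-1]
            assert len(set(hit.sequence)) >= 2
            assert "X" not in hit.sequence

    @given(st.text(alphabet=AA, min_size=5, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity_in_length_bounds(self, seq):
        chain = make_chain(seq)
        loose = len(enumerate_palindromes(chain, ScanConfig(min_len=4,
                                                            max_len=12)))
        base = len(enumerate_palindromes(chain, ScanConfig(min_len=5,
                                                           max_len=12)))
        tight = len(enumerate_palindromes(chain, ScanConfig(min_len=5,
                                                            max_len=7)))
        assert loose >= base >= tight

    @given(st.text(alphabet="AGLS", min_size=7, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_palindrome_closure(self, seq):
        """Every odd hit of length >= 7 has a co-centred hit of length L-2
        in the unfiltered enumeration."""
        chain = make_chain(seq)
        hits = {(h.start_index, h.length)
                for h in enumerate_palindromes(chain, ScanConfig(min_len=5,
                                                                 max_len=None))}
        for start, length in hits:
            if length >= 7 and length % 2 == 1:
                assert (start + 1, length - 2) in hits


class TestUniqueSequences:
    def test_multiplicity_across_chains(self):
        hits = [PalindromeHit("1EKQ", "A", 0, "AAIAA"),
                PalindromeHit("2RFR", "A", 5, "AAIAA")]
        uniq = unique_sequences(hits)
        assert set(uniq) == {5}
        assert uniq[5] == {"AAIAA": 2}

    def test_empty(self):
        assert unique_sequences([]) == {}

    def test_lengths_partition(self):
        hits = [PalindromeHit("X", "A", 0, "QKAKQ"),
                PalindromeHit("X", "A", 0, "AEQKAKQEA")]
        uniq = unique_sequences(hits)
        assert len(uniq[5]) == 1 and len(uniq[9]) == 1


class TestControls:
    @pytest.fixture()
    def chain_set(self):
        rng = np.random.default_rng(7)
        return [make_chain("".join(rng.choice(list(AA), size=80)),
                           pdb_id=f"SY{k:02d}") for k in range(5)]

    def test_cardinality_and_histogram(self, chain_set):
        hits = [h for c in chain_set for h in scan_chain(c)]
        # guarantee some hits even if the random chains have few
        hits += [PalindromeHit("SY00", "A", 0, chain_set[0].sequence[:5])
                 for _ in range(3)]
        hits = [h for h in hits if True]
        cfg = ScanConfig(seed=11)
        controls = sample_control_windows(chain_set, hits, cfg)
        assert len(controls) == len(hits)
        from collections import Counter
        assert Counter(h.length for h in hits) == \
            Counter(c.length for c in controls)
        for ctl in controls:
            assert ctl.sequence != ctl.sequence[::-1]

    def test_determinism(self, chain_set):
        hits = [h for c in chain_set for h in scan_chain(c)] or [
            PalindromeHit("SY00", "A", 0, chain_set[0].sequence[:5])]
        cfg = ScanConfig(seed=3)
        a = sample_control_windows(chain_set, hits, cfg)
        b = sample_control_windows(chain_set, hits, cfg)
        assert [(c.pdb_id, c.start_index, c.sequence) for c in a] == \
            [(c.pdb_id, c.start_index, c.sequence) for c in b]

    def test_impossible_control_raises(self):
        # a chain set where every window of length 5 is palindromic
        chain = make_chain("AAAAA")
        hit = PalindromeHit("TEST", "A", 0, "AAAAA")
        cfg = ScanConfig(seed=0, max_control_retries=50)
        with pytest.raises(RuntimeError, match="control"):
            sample_control_windows([chain], [hit], cfg)
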