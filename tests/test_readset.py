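"""Read ingestion, sentinel-order sorting and the containment prefilter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spmgraph.readset import (
    EncodedReadSet,
    FastaParseError,
    Read,
    encode,
    lex_sort_with_lcp,
    prefilter,
    read_fasta,
    revcomp,
    load_readset,
    save_readset,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_ambiguity_codes_dropped(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">a\nACGT\n>b\nACNT\n")
        reads = read_fasta(p)
        assert reads == [Read(1, "ACGT")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_case_folding(self, tmp_path):
        p = tmp_path / "lc.fa"
        p.write_text(">a\nacgt\n")
        assert read_fasta(p) == [Read(1, "ACGT")]

    def test_wrapped_lines(self, tmp_path):
        p = tmp_path / "w.fa"
        p.write_text(">a\nACGT\nACGT\n")
        assert read_fasta(p) == [Read(1, "ACGTACGT")]

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("\nACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="line 2"):
            read_fasta(p)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

class TestEncode:
    def test_reverse_complement_strand(self):
        E = encode([Read(1, "ACGTA")], l_min=3)
        assert E.m == 1 and E.n == 5
        assert "".join(E.base(2, p) for p in range(1, 6)) == "TACGT"

    def test_length_filter(self):
        E = encode([Read(1, "AC")], l_min=3)
        assert E.m == 0 and E.is_empty

    def test_homopolymer_complement(self):
        E = encode([Read(1, "AAAA")], l_min=1)
        assert E.strand_seq(2) == "TTTT"

    def test_rc_base_identity(self):
        # base(m+i, p) == complement of read i at |r|-p+1
        E = encode([Read(1, "ACCGT")], l_min=1)
        comp = dict(zip("ACGT", "TGCA"))
        s = E.strand_seq(1)
        for p in range(1, 6):
            assert E.base(2, p) == comp[s[len(s) - p]]

    def test_lengths_match_between_strands(self):
        E = encode([Read(1, "ACGTA"), Read(2, "ACG")], l_min=1)
        for i in (1, 2):
            assert E.length(i) == E.length(E.m + i)


# ---------------------------------------------------------------------------
# Sorting with lcp byproduct
# ---------------------------------------------------------------------------

def naive_sentinel_sort(E):
    """Independent oracle: sort sentinel-padded strings directly."""
    import functools

    def cmp(i, j):
        a, b = E.strand_seq(i), E.strand_seq(j)
        for x, y in zip(a, b):
            if x != y:
                return -1 if x < y else 1
        if len(a) != len(b):  # sentinel sorts after every base
            return -1 if len(a) > len(b) else 1
        return -1 if i < j else 1  # $_i < $_j

    return sorted(range(1, 2 * E.m + 1), key=functools.cmp_to_key(cmp))


class TestLexSort:
    def test_extension_sorts_before_prefix(self):
        # With sentinels > bases, "ACGT$" < "ACG$"
        E = EncodedReadSet(["ACGT", "ACG"])
        order, lcps = lex_sort_with_lcp(E)
        pos = {E.strand_seq(s): t for t, s in enumerate(order)}
        assert pos["ACGT"] < pos["ACG"]
        assert lcps[pos["ACGT"]] == 3

    def test_single_read(self):
        E = EncodedReadSet(["ACGTT"])
        order, lcps = lex_sort_with_lcp(E)
        assert len(order) == 2 and len(lcps) == 1

    def test_identical_reads_tie_by_index(self):
        E = EncodedReadSet(["ACGT", "ACGT"])
        order, lcps = lex_sort_with_lcp(E)
        first = [s for s in order if E.strand_seq(s) == "ACGT"]
        assert first == sorted(first)
        assert lcps[order.index(first[0])] == 4

    @given(st.lists(dna, min_size=1, max_size=20))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_naive_oracle(self, seqs):
        E = EncodedReadSet(seqs)
        order, lcps = lex_sort_with_lcp(E)
        assert order == naive_sentinel_sort(E)
        for t in range(len(order) - 1):
            a, b = E.strand_seq(order[t]), E.strand_seq(order[t + 1])
            k = 0
            while k < min(len(a), len(b)) and a[k] == b[k]:
                k += 1
            assert lcps[t] == k


# ---------------------------------------------------------------------------
# Prefilter
# ---------------------------------------------------------------------------

def oracle_removed(seqs):
    """Brute-force removal decisions: duplicates (keep the first copy of an
    identity class over both strands), then prefix/suffix containment
    against every strand of every other read."""
    m = len(seqs)
    strands = list(seqs) + [revcomp(s) for s in seqs]
    dup, pre, suf = set(), set(), set()
    for i in range(1, m + 1):
        s = seqs[i - 1]
        for j in range(1, m + 1):
            if j < i and (seqs[j - 1] == s or revcomp(seqs[j - 1]) == s):
                dup.add(i)
        fwd_prefix = any(len(t) > len(s) and t.startswith(s) for t in strands)
        rc = revcomp(s)
        rc_prefix = any(len(t) > len(rc) and t.startswith(rc) for t in strands)
        if i not in dup:
            if fwd_prefix:
                pre.add(i)
            elif rc_prefix:
                suf.add(i)
    # reads removed for any reason
    removed = dup | pre | suf
    for i in range(1, m + 1):
        s = seqs[i - 1]
        if any(len(t) > len(s) and t.startswith(s) for t in strands):
            removed.add(i)
        rc = revcomp(s)
        if any(len(t) > len(rc) and t.startswith(rc) for t in strands):
            removed.add(i)
    return removed, dup, pre, suf


class TestPrefilter:
    def test_worked_example(self):
        # ACGT is a prefix, CGTA a suffix (via RC), second ACGTA a duplicate
        E = EncodedReadSet(["ACGTA", "ACGT", "CGTA", "ACGTA"])
        kept, rep = prefilter(E)
        assert kept.forward_sequences() == ["ACGTA"]
        assert rep.kept_ids == [1]
        assert rep.kept_count + rep.removed_total == rep.input_count == 4
        assert rep.removed_duplicates == 1

    def test_cross_strand_duplicate(self):
        # ACGTT == revcomp(AACGT): the later copy is removed
        E = EncodedReadSet(["ACGTT", "AACGT"])
        kept, rep = prefilter(E)
        assert kept.forward_sequences() == ["ACGTT"]
        assert rep.removed_duplicates == 1

    def test_palindrome_survives(self):
        E = EncodedReadSet(["AAAA"])
        kept, rep = prefilter(E)
        assert kept.forward_sequences() == ["AAAA"]
        assert rep.removed_total == 0

    def test_duplicated_palindrome_keeps_one_copy(self):
        # both reads equal their own RC; exactly one copy must survive
        E = EncodedReadSet(["ACGT", "ACGT"])
        kept, rep = prefilter(E)
        assert kept.forward_sequences() == ["ACGT"]
        assert rep.removed_duplicates == 1

    @given(st.lists(dna, min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_kept_set_is_suffix_and_prefix_free(self, seqs):
        E = EncodedReadSet(seqs)
        kept, rep = prefilter(E)
        ks = kept.forward_sequences()
        strands = ks + [revcomp(s) for s in ks]
        for a in range(len(strands)):
            for b in range(len(strands)):
                if a == b:
                    continue
                sa, sb = strands[a], strands[b]
                if len(sa) < len(sb):
                    assert not sb.startswith(sa), (sa, sb)
                    assert not sb.endswith(sa), (sa, sb)
        assert rep.kept_count + rep.removed_total == rep.input_count

    @given(st.lists(dna, min_size=1, max_size=25))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_removed_set_and_counts_match_oracle(self, seqs):
        E = EncodedReadSet(seqs)
        kept, rep = prefilter(E)
        removed, dup, pre, suf = oracle_removed(seqs)
        assert set(rep.kept_ids) == set(range(1, len(seqs) + 1)) - removed
        assert rep.removed_duplicates == len(dup)
        assert rep.removed_prefix_contained == len(pre)
        assert rep.removed_suffix_contained == len(suf)

    @given(st.lists(dna, min_size=1, max_size=25))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_idempotent(self, seqs):
        E = EncodedReadSet(seqs)
        once, _ = prefilter(E)
        if once.is_empty:
            return
        twice, rep2 = prefilter(once)
        assert twice.forward_sequences() == once.forward_sequences()
        assert rep2.removed_total == 0


class TestSidecar:
    def test_round_trip(self, tmp_path):
        E = EncodedReadSet(["ACGTA", "TTTTC"], [3, 7])
        p = tmp_path / "rs.tsv"
        save_readset(E, p)
        back = load_readset(p)
        assert back.forward_sequences() == E.forward_sequences()
        assert list(back.read_ids) == [3, 7]

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("not a sidecar\n")
        with pytest.raises(ValueError):
            load_readset(p)
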