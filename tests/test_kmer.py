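"""Unit and property tests for k-mer indexing, scanning and copy calling."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitokmer import (
    KmerMatch,
    build_kmer_index,
    call_copies,
    cluster_matches,
    scan_read,
)
from mitokmer._seq import random_dna, revcomp


def brute_force_scan(read: str, query: str, k: int):
    """Independent oracle: dictionary scan over literal k-mer strings."""
    table = {}
    rc = revcomp(query)
    L = len(query)
    for p in range(L - k + 1):
        for seq, strand in ((query, "+"), (rc, "-")):
            kmer = seq[p : p + k]
            if set(kmer) <= set("ACGT"):
                table.setdefault(kmer, []).append((p, strand))
    out = []
    for r in range(len(read) - k + 1):
        kmer = read[r : r + k]
        if set(kmer) <= set("ACGT"):
            for p, strand in table.get(kmer, ()):
                out.append((r, p, strand))
    return sorted(out)


class TestIndex:
    def test_enumerates_both_strands(self):
        idx = build_kmer_index("ACGTACGTA", 8)
        assert idx.k == 8 and idx.query_length == 9
        assert idx.entries == {
            "ACGTACGT": [(0, "+"), (1, "-")],
            "CGTACGTA": [(1, "+")],
            "TACGTACG": [(0, "-")],
        }

    def test_unique_kmer_count(self, rng):
        query = random_dna(rng, 400)
        k = 19
        assert len({query[i : i + k] for i in range(400 - k + 1)}) == 382
        idx = build_kmer_index(query, k)
        fwd = sum(1 for v in idx.entries.values() for _, s in v if s == "+")
        assert fwd == 400 - 18

    def test_ambiguous_kmers_absent(self):
        idx = build_kmer_index("AAANAAAA", 3)
        for kmer in idx.entries:
            assert "N" not in kmer
        positions = {p for v in idx.entries.values() for p, s in v if s == "+"}
        assert positions == {0, 4, 5}  # AAA windows not overlapping the N

    @pytest.mark.parametrize("query", ["", "ACGTACGTACGTACGTAC"])
    def test_query_too_short(self, query):
        with pytest.raises(ValueError, match="query too short"):
            build_kmer_index(query, 19)


class TestScan:
    def test_identity_and_reverse_symmetry(self, rng):
        query = random_dna(rng, 150)
        idx = build_kmer_index(query, 19)
        fwd = scan_read(query, idx)
        assert len(fwd) == 150 - 18
        assert all(m.strand == "+" and m.read_position == m.query_position for m in fwd)
        rev = scan_read(revcomp(query), idx)
        assert len(rev) == len(fwd)
        assert all(m.strand == "-" for m in rev)

    def test_random_pair_no_matches(self, rng):
        query, read = random_dna(rng, 528), random_dna(rng, 5000)
        assert brute_force_scan(read, query, 19) == []
        assert scan_read(read, build_kmer_index(query, 19)) == []

    def test_matches_brute_force_oracle(self, rng):
        query = random_dna(rng, 60)
        read = random_dna(rng, 80) + query + random_dna(rng, 40) + revcomp(query)
        idx = build_kmer_index(query, 13)
        got = [(m.read_position, m.query_position, m.strand) for m in scan_read(read, idx)]
        assert sorted(got) == brute_force_scan(read, query, 13)

    def test_short_read_empty(self, rng):
        idx = build_kmer_index(random_dna(rng, 50), 19)
        assert scan_read("ACGT", idx) == []


class TestCluster:
    @staticmethod
    def _matches(positions):
        return [KmerMatch(p, i, "+") for i, p in enumerate(positions)]

    def test_gap_rule_partitions(self):
        matches = self._matches([100, 119, 138, 1200, 1219])
        blocks = cluster_matches(matches, 800, k=19, query_length=600)
        assert [(b.read_start, b.read_end) for b in blocks] == [(100, 157), (1200, 1238)]
        assert len(cluster_matches(matches, 2000, k=19, query_length=600)) == 1

    def test_empty_and_invalid(self):
        assert cluster_matches([], 800, k=19, query_length=100) == []
        with pytest.raises(ValueError, match="invalid threshold"):
            cluster_matches(self._matches([1]), 0, k=19, query_length=100)

    def test_block_internal_gap_bounded(self, rng):
        matches = self._matches([0, 50, 700, 1400, 1450])
        blocks = cluster_matches(matches, 700, k=19, query_length=2000)
        for block in blocks:
            member = [m.read_position for m in matches
                      if block.read_start <= m.read_position < block.read_end]
            gaps = np.diff(member)
            assert (gaps <= 700).all()


class TestCallCopies:
    def test_read_equals_query(self, rng):
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        call = call_copies(query, idx)
        assert call.copy_count == 1
        assert call.blocks[0].query_coverage == 1.0

    def test_two_copies_with_short_spacer(self, rng):
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        read = random_dna(rng, 1000) + query + random_dna(rng, 300) + query \
            + random_dna(rng, 1000)
        assert call_copies(read, idx).copy_count == 2

    def test_truncated_copies_counted(self, rng):
        # two full + two half-length copies, as in a degenerating tandem
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        half = query[: len(query) // 2]
        spacer = lambda: random_dna(rng, 900)  # noqa: E731
        read = (random_dna(rng, 700) + query + spacer() + half + spacer()
                + query + spacer() + half + random_dna(rng, 700))
        call = call_copies(read, idx, min_query_coverage=0.25)
        assert call.copy_count == 4

    @pytest.mark.parametrize("c", range(6))
    def test_copy_count_oracle(self, c, rng):
        """Error-free reads with c embedded copies yield exactly c,
        regardless of orientation, even at 1-nt copy separation."""
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        parts = [random_dna(rng, 600)]
        for i in range(c):
            parts.append(query)
            parts.append(random_dna(rng, 1 + 400 * (i % 2)))
        parts.append(random_dna(rng, 600))
        read = "".join(parts)
        fwd = call_copies(read, idx)
        rev = call_copies(revcomp(read), idx)
        assert fwd.copy_count == c == rev.copy_count
        assert sorted(b.strand for b in fwd.blocks) == sorted(
            {"+": "-", "-": "+"}[b.strand] for b in rev.blocks
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.integers(0, 4))
    def test_orientation_invariance_property(self, seed, c):
        rng = np.random.default_rng(seed)
        query = random_dna(rng, 300)
        idx = build_kmer_index(query, 19)
        read = random_dna(rng, 400)
        for _ in range(c):
            read += query + random_dna(rng, int(rng.integers(1, 1200)))
        assert call_copies(read, idx).copy_count == \
            call_copies(revcomp(read), idx).copy_count == c

    def test_monotonicity_in_thresholds(self, rng):
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        read = random_dna(rng, 500)
        for gap in (900, 1500, 300):
            read += query + random_dna(rng, gap)
        matches = scan_read(read, idx)
        n_blocks = [
            len(cluster_matches(matches, g, k=19, query_length=528))
            for g in (100, 400, 800, 1600, 5000)
        ]
        assert n_blocks == sorted(n_blocks, reverse=True)
        counts_k = [call_copies(read, idx, min_kmers=mk).copy_count
                    for mk in (1, 5, 50, 200, 1000)]
        assert counts_k == sorted(counts_k, reverse=True)
        counts_cov = [call_copies(read, idx, min_query_coverage=mc).copy_count
                      for mc in (0.0, 0.1, 0.5, 0.9, 1.01)]
        assert counts_cov == sorted(counts_cov, reverse=True)

    def test_error_tolerance_three_copy_reads(self):
        """>=95% of 3-copy reads survive 10% indel-dominated noise."""
        from mitokmer._seq import decode, encode
        from mitokmer.simulate import ErrorModel, _apply_errors

        rng = np.random.default_rng(1234)
        query = random_dna(rng, 528)
        idx = build_kmer_index(query, 19)
        em = ErrorModel(sub_rate=0.01, ins_rate=0.055, del_rate=0.035)
        ok = 0
        n = 80
        for _ in range(n):
            read = random_dna(rng, 800)
            for _ in range(3):
                read += query + random_dna(rng, 900)
            noisy = decode(_apply_errors(encode(read), em, rng))
            ok += call_copies(noisy, idx).copy_count == 3
        assert ok / n >= 0.95
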