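"""Exact k-mer matching of a query against long reads, clustered into blocks.

This is the computational core of the pipeline: a query gene (e.g. *ND6*)
is k-merized on both strands and searched within each raw read. Runs of
matching k-mers are clustered into *matching blocks* under a maximum-gap
rule: if two matching k-mers lie more than ``gap_threshold`` nucleotides
apart on the read they belong to different blocks, i.e. to different
putative gene copies. With the defaults (k=19, gap 800 nt) a block count
over a read is a direct, alignment-free estimate of how many copies of the
query the read carries, tolerant of the indel-dominated errors of PacBio
CLR data because only a fraction of k-mers need to survive.

Coordinates are 0-based half-open throughout this module; reporting code
converts to 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._seq import encode, kmer_codes, revcomp


class KmerMatch(NamedTuple):
    """A single query<->read k-mer match."""

    read_position: int
    query_position: int
    strand: str


@dataclass(frozen=True)
class MatchBlock:
    """A clustered run of k-mer matches on one read.

    ``read_start``/``read_end`` delimit the block on the read (half-open);
    ``strand`` is the majority orientation of member matches;
    ``query_coverage`` is the fraction of query positions covered by the
    member k-mers (in forward query coordinates, whichever strand matched).
    """

    read_start: int
    read_end: int
    strand: str
    n_kmers: int
    query_coverage: float

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class CopyCall:
    """Per-read copy count of a query gene: blocks passing support filters."""

    read_id: str | None
    read_length: int
    copy_count: int
    blocks: list[MatchBlock]
    n_blocks: int  # total blocks before support filtering


@dataclass
class KmerIndex:
    """Both-strand k-mer index of a query sequence.

    Strand '-' entries are the reverse complements of forward k-mers,
    stored at the mirrored offset ``query_length - k - p`` so that a read
    equal to the reverse complement of the query produces matches on the
    diagonal. k-mers containing ambiguous bases are absent.
    """

    k: int
    query_length: int
    _codes: np.ndarray = field(repr=False)   # sorted unique k-mer codes
    _starts: np.ndarray = field(repr=False)  # group offsets, len = len(_codes)+1
    _qpos: np.ndarray = field(repr=False)    # entry query positions, grouped
    _strand: np.ndarray = field(repr=False)  # entry strands, 0='+', 1='-'

    @property
    def n_entries(self) -> int:
        return int(self._qpos.size)

    @property
    def entries(self) -> dict[str, list[tuple[int, str]]]:
        """Map k-mer string -> [(query_position, strand), ...] (built on demand)."""
        out: dict[str, list[tuple[int, str]]] = {}
        k = self.k
        for i, code in enumerate(self._codes):
            s = ""
            c = int(code)
            for _ in range(k):
                s = "ACGT"[c & 3] + s
                c >>= 2
            lo, hi = int(self._starts[i]), int(self._starts[i + 1])
            out[s] = [
                (int(self._qpos[j]), "+" if self._strand[j] == 0 else "-")
                for j in range(lo, hi)
            ]
        return out


def build_kmer_index(query: str, k: int) -> KmerIndex:
    """Index every unambiguous k-mer of ``query`` on both strands.

    Raises ``ValueError("query too short")`` when the query is shorter
    than k (including the empty query).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(query) < k:
        raise ValueError("query too short")
    fwd = encode(query)
    rc = encode(revcomp(query))
    fc, fv = kmer_codes(fwd, k)
    rcodes, rv = kmer_codes(rc, k)
    n = fc.size
    pos = np.arange(n, dtype=np.int64)
    codes = np.concatenate([fc[fv], rcodes[rv]])
    qpos = np.concatenate([pos[fv], pos[rv]])
    strand = np.concatenate(
        [np.zeros(int(fv.sum()), np.int8), np.ones(int(rv.sum()), np.int8)]
    )
    order = np.argsort(codes, kind="stable")
    codes, qpos, strand = codes[order], qpos[order], strand[order]
    uniq, counts = np.unique(codes, return_counts=True)
    starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return KmerIndex(k=k, query_length=len(query), _codes=uniq, _starts=starts,
                     _qpos=qpos, _strand=strand)


def _scan_arrays(read: str, index: KmerIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised scan; returns (read_pos, query_pos, strand) sorted by read_pos."""
    empty = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int8))
    if len(read) < index.k:
        return empty
    codes, valid = kmer_codes(encode(read), index.k)
    rpos = np.nonzero(valid)[0]
    c = codes[rpos]
    if c.size == 0 or index._codes.size == 0:
        return empty
    loc = np.searchsorted(index._codes, c)
    loc_c = np.minimum(loc, index._codes.size - 1)
    hit = index._codes[loc_c] == c
    rpos, loc_c = rpos[hit], loc_c[hit]
    if rpos.size == 0:
        return empty
    starts = index._starts
    counts = starts[loc_c + 1] - starts[loc_c]
    out_rpos = np.repeat(rpos, counts)
    # concatenated-ranges trick: entry indices for every hit group
    total = int(counts.sum())
    step = np.ones(total, np.int64)
    head = np.cumsum(counts)[:-1]
    step[0] = starts[loc_c[0]]
    if head.size:
        step[head] = starts[loc_c[1:]] - (starts[loc_c[:-1]] + counts[:-1] - 1)
    eidx = np.cumsum(step)
    return out_rpos, index._qpos[eidx], index._strand[eidx]


def scan_read(read: str, index: KmerIndex) -> list[KmerMatch]:
    """All positions where a read k-mer equals an indexed k-mer.

    Sorted by read position; a read shorter than k yields an empty list.
    """
    rpos, qpos, strand = _scan_arrays(read, index)
    return [
        KmerMatch(int(r), int(q), "+" if s == 0 else "-")
        for r, q, s in zip(rpos, qpos, strand)
    ]


def _matches_to_arrays(matches: Sequence[KmerMatch]):
    rpos = np.fromiter((m.read_position for m in matches), np.int64, len(matches))
    qpos = np.fromiter((m.query_position for m in matches), np.int64, len(matches))
    strand = np.fromiter(
        ((0 if m.strand == "+" else 1) for m in matches), np.int8, len(matches)
    )
    return rpos, qpos, strand


def _block_from(
    r: np.ndarray, q: np.ndarray, s: np.ndarray, k: int, query_length: int
) -> MatchBlock:
    n_minus = int(s.sum())
    n_plus = r.size - n_minus
    if n_plus > n_minus:
        bstrand = "+"
    elif n_minus > n_plus:
        bstrand = "-"
    else:  # tie: strand of the member with the smallest query position
        bstrand = "+" if s[np.argmin(q)] == 0 else "-"
    # coverage in forward query coordinates; '-' entries are stored at
    # mirrored offsets, so their forward footprint is [L-k-q, L-q)
    fstart = np.where(s == 0, q, query_length - k - q)
    diff = np.zeros(query_length + 1, np.int32)
    np.add.at(diff, fstart, 1)
    np.add.at(diff, fstart + k, -1)
    covered = int(np.count_nonzero(np.cumsum(diff[:-1]) > 0))
    return MatchBlock(
        read_start=int(r[0]),
        read_end=int(r[-1]) + k,
        strand=bstrand,
        n_kmers=int(r.size),
        query_coverage=covered / query_length,
    )


def _gap_segments(rpos: np.ndarray, gap_threshold: int) -> list[np.ndarray]:
    cut = np.nonzero(np.diff(rpos) > gap_threshold)[0] + 1
    return np.split(np.arange(rpos.size), cut)


def _cluster_arrays(
    rpos: np.ndarray,
    qpos: np.ndarray,
    strand: np.ndarray,
    gap_threshold: int,
    k: int,
    query_length: int,
) -> list[MatchBlock]:
    if gap_threshold < 1:
        raise ValueError("invalid threshold")
    if rpos.size == 0:
        return []
    order = np.lexsort((qpos, rpos))
    rpos, qpos, strand = rpos[order], qpos[order], strand[order]
    return [
        _block_from(rpos[seg], qpos[seg], strand[seg], k, query_length)
        for seg in _gap_segments(rpos, gap_threshold)
    ]


def _restart_groups(rpos: np.ndarray, qpos: np.ndarray, k: int) -> list[np.ndarray]:
    """Split same-strand matches of one gap-block at query restarts.

    Within one gene copy the matched query offsets progress with the read
    (modulo small indel jitter); a new copy announces itself by the query
    offset dropping back towards zero. Matches are chained greedily: at
    each read position the smallest query offset >= (previous − k) is the
    continuation; if none exists the copy ends and a new one starts. This
    separates tandem copies lying closer than the gap threshold (even
    1 nt apart) and is insensitive to k-mers repeated within the query,
    which always offer a forward continuation.
    """
    n = rpos.size
    idx = np.arange(n)
    if n == 0:
        return []
    unique_r = bool(np.all(np.diff(rpos) > 0))
    if unique_r:  # fast path: one candidate offset per read position
        cuts = np.nonzero(np.diff(qpos) < -k)[0] + 1
        return np.split(idx, cuts)
    groups: list[np.ndarray] = []
    start = 0
    prev = None
    i = 0
    while i < n:
        j = i
        while j < n and rpos[j] == rpos[i]:
            j += 1
        cand = qpos[i:j]
        if prev is None:
            prev = int(cand.min())
        else:
            cont = cand[cand >= prev - k]
            if cont.size:
                prev = int(cont.min())
            else:
                groups.append(idx[start:i])
                start = i
                prev = int(cand.min())
        i = j
    groups.append(idx[start:n])
    return groups


def cluster_matches(
    matches: Sequence[KmerMatch],
    gap_threshold: int,
    *,
    k: int,
    query_length: int,
) -> list[MatchBlock]:
    """Partition matches into blocks under the maximum-gap rule.

    Successive read positions within a block differ by <= ``gap_threshold``;
    between consecutive blocks by more. Matches are re-sorted defensively.
    """
    rpos, qpos, strand = _matches_to_arrays(matches)
    return _cluster_arrays(rpos, qpos, strand, gap_threshold, k, query_length)


def call_copies(
    read: str,
    index: KmerIndex,
    gap_threshold: int = 800,
    min_kmers: int = 5,
    min_query_coverage: float = 0.1,
    read_id: str | None = None,
) -> CopyCall:
    """Count putative query-gene copies on one read.

    Copies are delimited twice: matches further apart than
    ``gap_threshold`` on the read belong to different copies (the gap
    rule), and within a gap-block a restart of the query coordinate marks
    abutting copies (see ``_restart_groups``). A copy counts when its
    block has at least ``min_kmers`` member matches and covers at least
    ``min_query_coverage`` of the query — the support filters that keep
    genuine (possibly truncated) gene copies while rejecting random
    k-mer matches.
    """
    if min_kmers < 0 or min_query_coverage < 0:
        raise ValueError("support thresholds must be >= 0")
    if gap_threshold < 1:
        raise ValueError("invalid threshold")
    rpos, qpos, strand = _scan_arrays(read, index)
    k, qlen = index.k, index.query_length
    order = np.lexsort((qpos, rpos))
    rpos, qpos, strand = rpos[order], qpos[order], strand[order]
    blocks: list[MatchBlock] = []
    if rpos.size:
        for seg in _gap_segments(rpos, gap_threshold):
            for sval in (0, 1):
                sub = seg[strand[seg] == sval]
                if sub.size == 0:
                    continue
                for grp in _restart_groups(rpos[sub], qpos[sub], k):
                    g = sub[grp]
                    blocks.append(_block_from(rpos[g], qpos[g], strand[g], k, qlen))
    blocks.sort(key=lambda b: (b.read_start, b.read_end))
    passing = [
        b
        for b in blocks
        if b.n_kmers >= min_kmers and b.query_coverage >= min_query_coverage
    ]
    return CopyCall(
        read_id=read_id,
        read_length=len(read),
        copy_count=len(passing),
        blocks=passing,
        n_blocks=len(blocks),
    )
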