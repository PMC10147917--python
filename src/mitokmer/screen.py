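"""Selection of mitochondrial reads and of reads spanning the duplicated region.

Two screens, both built on k-mer matching blocks:

* *mt screen* — a read is mitochondrial when its longest matching block
  against the whole reference mitogenome spans at least ``min_block``
  nucleotides (default 5000 nt; 3000 nt for lower-yield libraries). NuMT
  inserts, being short, cannot produce such a block, so requiring a long
  block avoids nuclear-mitochondrial contamination.
* *anchor screen* — among mt reads, those carrying matching blocks for
  both flanking anchor genes (*12S* and *CYTB* by default) span the
  region that contains the tandem-duplicated *ND6*/*trnE*/*trnP*/CR
  block, and are the reads on which copy counts are comparable.

The reference is indexed over its doubled sequence (seq+seq) so reads
crossing the origin of the circular mitogenome form a single block.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .kmer import KmerIndex, _cluster_arrays, _scan_arrays, build_kmer_index, call_copies


@dataclass
class AnchorPair:
    """The two anchor genes flanking the duplicated region."""

    left_name: str
    right_name: str
    left_seq: str
    right_seq: str
    _indices: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.left_name == self.right_name:
            raise ValueError("anchor names must be distinct")

    def indices(self, k: int) -> tuple[KmerIndex, KmerIndex]:
        if k not in self._indices:
            self._indices[k] = (
                build_kmer_index(self.left_seq, k),
                build_kmer_index(self.right_seq, k),
            )
        return self._indices[k]

    @classmethod
    def from_genes(
        cls, genes: Mapping[str, str], left: str = "12S", right: str = "CYTB"
    ) -> "AnchorPair":
        for name in (left, right):
            if name not in genes:
                raise KeyError(f"anchor gene not found: {name}")
        return cls(left, right, genes[left], genes[right])


@dataclass
class ScreenResult:
    read_id: str
    read_length: int
    mt_block_span: int
    is_mt: bool
    spans_anchors: bool
    anchor_orientation: str  # '+', '-', 'mixed', 'na'
    anchor_side: str = "na"  # 'duplicated', 'opposite', 'na'


def _anchor_blocks(read, anchors, k, gap_threshold, min_kmers, min_query_coverage):
    left_idx, right_idx = anchors.indices(k)
    best = []
    for idx in (left_idx, right_idx):
        call = call_copies(read, idx, gap_threshold, min_kmers, min_query_coverage)
        if not call.blocks:
            return None
        best.append(max(call.blocks, key=lambda b: b.n_kmers))
    return best


def spans_anchor_pair(
    read: str,
    anchors: AnchorPair,
    k: int = 19,
    gap_threshold: int = 800,
    min_kmers: int = 5,
    min_query_coverage: float = 0.1,
) -> tuple[bool, str]:
    """Whether a read carries passing blocks for both anchor genes.

    Returns (spans, orientation); orientation is '+' when the best block
    of each anchor is on strand '+', '-' when both are on '-', 'mixed'
    otherwise, and 'na' when the read does not span.
    """
    best = _anchor_blocks(read, anchors, k, gap_threshold, min_kmers,
                          min_query_coverage)
    if best is None:
        return False, "na"
    if best[0].strand == best[1].strand:
        return True, best[0].strand
    return True, "mixed"


def anchor_side(
    read: str,
    anchors: AnchorPair,
    k: int = 19,
    gap_threshold: int = 800,
    min_kmers: int = 5,
    min_query_coverage: float = 0.1,
) -> tuple[bool, str, str]:
    """Which side of the circle a both-anchor read runs through.

    A read carrying both anchors traverses exactly one of the two arcs
    between them. With the canonical layout (left anchor *12S* near the
    origin, right anchor *CYTB* upstream of the duplicated block), a
    forward-strand read through the duplicated side shows the right
    anchor before the left one; the order flips on '-' reads. Returns
    (spans, orientation, side) with side in {'duplicated', 'opposite',
    'na'} ('na' for non-spanning or mixed-orientation reads).
    """
    best = _anchor_blocks(read, anchors, k, gap_threshold, min_kmers,
                          min_query_coverage)
    if best is None:
        return False, "na", "na"
    left, right = best
    if left.strand != right.strand:
        return True, "mixed", "na"
    orient = left.strand
    right_first = right.read_start < left.read_start
    duplicated = right_first if orient == "+" else not right_first
    return True, orient, "duplicated" if duplicated else "opposite"


def screen_mt_reads(
    reads: Iterable[tuple[str, str]],
    reference: str,
    k: int = 19,
    gap_threshold: int = 800,
    min_block: int = 5000,
    anchors: AnchorPair | None = None,
    min_kmers: int = 5,
    min_query_coverage: float = 0.1,
) -> list[ScreenResult]:
    """Screen a read pool against a circular reference mitogenome.

    ``reads`` is an iterable of (read_id, sequence). A read is
    mitochondrial when its longest matching block spans >= ``min_block``
    nt. When ``anchors`` is given, mt reads are additionally tested for
    anchor spanning (non-mt reads never span, preserving the invariant
    spans_anchors => is_mt).
    """
    if not reference:
        raise ValueError("empty reference")
    if min_block <= 0:
        raise ValueError("min_block must be > 0")
    index = build_kmer_index(reference + reference, k)
    results = []
    for read_id, seq in reads:
        rpos, qpos, strand = _scan_arrays(seq, index)
        blocks = _cluster_arrays(
            rpos, qpos, strand, gap_threshold, k, index.query_length
        )
        span = max((b.span for b in blocks), default=0)
        is_mt = span >= min_block
        spans, orient, side = False, "na", "na"
        if is_mt and anchors is not None:
            spans, orient, side = anchor_side(
                seq, anchors, k, gap_threshold, min_kmers, min_query_coverage
            )
        results.append(
            ScreenResult(
                read_id=read_id,
                read_length=len(seq),
                mt_block_span=span,
                is_mt=is_mt,
                spans_anchors=spans,
                anchor_orientation=orient,
                anchor_side=side,
            )
        )
    return results
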