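"""Gene-block decomposition and rearrangement classification.

A target mitogenome (assembly or single long read) is decomposed into an
ordered, stranded list of reference-gene matching blocks; rearrangements
are then classified on the resulting *gene-label string*, which is robust
to sequence divergence:

* ``tandem_duplication`` — a maximal gene subsequence repeated >= 2 times
  consecutively; the unit is the shortest (primitive) repeating string.
* ``remnant_block`` — adjacent to a duplication of unit U, a consecutive
  proper suffix of U (e.g. trnP,CR beside full ND6,trnE,trnP,CR copies),
  the footprint of a partially lost extra copy.
* ``inversion`` — a maximal run of >= 2 consecutive blocks on strand '-'
  whose label order is reversed relative to the canonical vertebrate
  order; the span covers the run's extent in target coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .kmer import build_kmer_index, call_copies

#: Canonical vertebrate mitogenome gene order (heavy-strand sense).
VERTEBRATE_ORDER = [
    "trnF", "12S", "trnV", "16S", "trnL1", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "trnC", "trnY", "COX1", "trnS1", "trnD",
    "COX2", "trnK", "ATP8", "ATP6", "COX3", "trnG", "ND3", "trnR", "ND4L",
    "ND4", "trnH", "trnS2", "trnL2", "ND5", "ND6", "trnE", "CYTB", "trnT",
    "trnP", "CR",
]


@dataclass(frozen=True)
class GeneBlock:
    gene: str
    start: int
    end: int  # may exceed target_length for blocks wrapping a circular origin
    strand: str
    query_coverage: float
    n_kmers: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class BlockDecomposition:
    blocks: list[GeneBlock]
    target_length: int
    circular: bool

    @property
    def labels(self) -> list[str]:
        return [b.gene for b in self.blocks]


@dataclass(frozen=True)
class RearrangementEvent:
    type: str  # 'tandem_duplication' | 'remnant_block' | 'inversion'
    unit: tuple[str, ...]
    n_copies: int
    span: int
    evidence: str


def decompose(
    target: str,
    reference_genes: Mapping[str, str],
    k: int = 19,
    gap_threshold: int = 800,
    min_kmers: int = 5,
    min_query_coverage: float = 0.1,
    circular: bool = False,
    rotate_to: str = "trnF",
) -> BlockDecomposition:
    """Locate every reference gene in the target as stranded blocks.

    Circular targets are searched over the doubled sequence so blocks may
    cross the origin, and the result is rotated so the block of
    ``rotate_to`` (default *trnF*, the first canonical gene) starts near
    zero. Emits a warning (not an error) when no gene is located.
    """
    L = len(target)
    subject = target + target if circular else target
    blocks: list[GeneBlock] = []
    for gene, qseq in reference_genes.items():
        if len(qseq) < k:
            raise ValueError(f"reference gene {gene!r} shorter than k={k}")
        idx = build_kmer_index(qseq, k)
        call = call_copies(subject, idx, gap_threshold, min_kmers, min_query_coverage)
        for b in call.blocks:
            blocks.append(
                GeneBlock(gene, b.read_start, b.read_end, b.strand,
                          b.query_coverage, b.n_kmers)
            )
    if circular:
        blocks = [b for b in blocks if b.start < L]
        # drop same-gene blocks circularly contained in another (origin-
        # crossing blocks also appear as clipped fragments of the doubling)
        def _contained(a: GeneBlock, b: GeneBlock) -> bool:
            return ((a.start - b.start) % L) + a.span <= b.span
        blocks = [
            a for a in blocks
            if not any(
                b is not a and a.gene == b.gene and _contained(a, b)
                and (a.span < b.span or (a.span == b.span and a.start > b.start))
                for b in blocks
            )
        ]
        rot_blocks = [b for b in blocks if b.gene == rotate_to]
        if rot_blocks:
            rot = min(b.start for b in rot_blocks) % L
            blocks = [
                GeneBlock(b.gene, (b.start - rot) % L, (b.start - rot) % L + b.span,
                          b.strand, b.query_coverage, b.n_kmers)
                for b in blocks
            ]
    blocks.sort(key=lambda b: (b.start, b.end))

    # collapse conflicting calls: >50% overlap of the shorter block keeps
    # the higher-coverage call (nested tRNA/rRNA margins overlap less)
    kept: list[GeneBlock] = []
    for b in blocks:
        if kept:
            prev = kept[-1]
            overlap = min(prev.end, b.end) - max(prev.start, b.start)
            if overlap > 0.5 * min(prev.span, b.span):
                if b.query_coverage > prev.query_coverage:
                    kept[-1] = b
                continue
        kept.append(b)
    if not kept:
        warnings.warn("decomposition empty", stacklevel=2)
    return BlockDecomposition(blocks=kept, target_length=L, circular=circular)


def _is_primitive(unit: Sequence[str]) -> bool:
    u = len(unit)
    for p in range(1, u):
        if u % p == 0 and all(unit[i] == unit[i % p] for i in range(u)):
            return False
    return True


def _circular_subsequence(labels: Sequence[str], order: Sequence[str]) -> bool:
    """True when ``labels`` appear in this relative order on the circular
    canonical gene order (one wrap allowed)."""
    doubled = list(order) + list(order)
    i = 0
    for lab in labels:
        while i < len(doubled) and doubled[i] != lab:
            i += 1
        if i == len(doubled):
            return False
        i += 1
    return True


def _rotate_for_classification(decomp: BlockDecomposition,
                               canonical_order: Sequence[str]) -> list[GeneBlock]:
    blocks = sorted(decomp.blocks, key=lambda b: (b.start, b.end))
    if not decomp.circular or not blocks:
        return blocks
    anchor = canonical_order[0]
    idx = next((i for i, b in enumerate(blocks) if b.gene == anchor), 0)
    return blocks[idx:] + blocks[:idx]


def classify_events(
    decomposition: BlockDecomposition,
    canonical_order: Sequence[str] = VERTEBRATE_ORDER,
) -> list[RearrangementEvent]:
    """Classify tandem duplications, remnant blocks and inversions.

    Operates on the gene-label sequence of the decomposition (rotated to
    the first canonical gene for circular targets, making the result
    rotation-invariant). Returns events in a deterministic order.
    """
    blocks = _rotate_for_classification(decomposition, canonical_order)
    labels = [b.gene for b in blocks]
    n = len(labels)
    L = decomposition.target_length
    events: list[RearrangementEvent] = []

    def _span(i: int, j: int) -> int:
        """Target-coordinate extent from block i through block j inclusive."""
        raw = blocks[j % n].end - blocks[i % n].start
        if decomposition.circular:
            return (raw - 1) % L + 1 if raw != 0 else L
        return raw

    # --- tandem duplications (shortest primitive repeating unit) ---
    candidates: list[tuple[int, int, int]] = []  # (start, unit_len, n_copies)
    for u in range(1, n // 2 + 1):
        i = 0
        while i + 2 * u <= n:
            unit = labels[i : i + u]
            if not _is_primitive(unit):
                i += 1
                continue
            r = 1
            while labels[i + r * u : i + (r + 1) * u] == unit:
                r += 1
            # keep all phases of maximal runs; the sort below arbitrates
            if r >= 2 and labels[i - u : i] != unit:
                candidates.append((i, u, r))
            i += 1

    def _adjacent_suffix_len(i: int, u: int, r: int) -> int:
        """Longest proper suffix of the unit sitting right next to the run.

        Arbitrates between phases of the same tandem array: the phase
        whose flanking residue forms the longest partial unit is the
        biologically meaningful one (remnants retain unit suffixes)."""
        unit = labels[i : i + u]
        for s in range(u - 1, 0, -1):
            if i - s >= 0 and labels[i - s : i] == unit[u - s :]:
                return s
            j = i + u * r
            if labels[j : j + s] == unit[u - s :]:
                return s
        return 0

    accepted: list[tuple[int, int, int]] = []
    used: set[int] = set()
    for i, u, r in sorted(
        candidates,
        key=lambda c: (-c[2], c[1], -_adjacent_suffix_len(*c), c[0]),
    ):
        span_idx = set(range(i, i + u * r))
        if span_idx & used:
            continue
        used |= span_idx
        accepted.append((i, u, r))

    for i, u, r in sorted(accepted):
        unit = tuple(labels[i : i + u])
        events.append(
            RearrangementEvent(
                type="tandem_duplication",
                unit=unit,
                n_copies=r,
                span=_span(i, i + u * r - 1),
                evidence=f"{r} consecutive copies of ({' '.join(unit)}) "
                         f"starting at block {i}",
            )
        )
        # remnant: a consecutive proper suffix of the unit adjacent to the run
        for s in range(u - 1, 0, -1):
            left = i - s >= 0 and labels[i - s : i] == list(unit[u - s :])
            j = i + u * r
            right = labels[j : j + s] == list(unit[u - s :])
            if left or right:
                at = i - s if left else j
                events.append(
                    RearrangementEvent(
                        type="remnant_block",
                        unit=unit[u - s :],
                        n_copies=1,
                        span=_span(at, at + s - 1),
                        evidence="partial duplicate unit; missing prefix: "
                                 + " ".join(unit[: u - s]),
                    )
                )
                break

    # --- inversions: maximal '-' runs, order reversed vs canonical ---
    strands = [b.strand for b in blocks]
    if n:
        runs: list[tuple[int, int]] = []
        if decomposition.circular and all(s == "-" for s in strands):
            runs = [(0, n)]
        elif decomposition.circular:
            # scan one full turn starting from a '+' block so '-' runs
            # wrapping the origin are seen whole
            p = strands.index("+")
            t = p
            while t < p + n:
                if strands[t % n] == "-":
                    j = t
                    while j < p + n and strands[j % n] == "-":
                        j += 1
                    runs.append((t, j))
                    t = j
                else:
                    t += 1
        else:
            i = 0
            while i < n:
                if strands[i] == "-":
                    j = i
                    while j < n and strands[j] == "-":
                        j += 1
                    runs.append((i, j))
                    i = j
                else:
                    i += 1
        for i, j in runs:
            if j - i < 2:
                continue
            run_labels = [labels[x % n] for x in range(i, j)]
            if not _circular_subsequence(run_labels[::-1], canonical_order):
                continue
            events.append(
                RearrangementEvent(
                    type="inversion",
                    unit=tuple(run_labels),
                    n_copies=1,
                    span=_span(i, j - 1),
                    evidence="strand '-' run with reversed canonical order",
                )
            )
    return events


def architecture_string(decomposition: BlockDecomposition) -> str:
    """Compact text architecture, e.g. ``trnT (ND6 trnE trnP CR)x3 trnF``.

    Duplication units are folded; '-' strand genes carry a '~' prefix.
    """
    blocks = sorted(decomposition.blocks, key=lambda b: (b.start, b.end))
    labels = [(b.gene if b.strand == "+" else "~" + b.gene) for b in blocks]
    plain = [b.gene for b in blocks]
    events = [
        e for e in classify_events(decomposition) if e.type == "tandem_duplication"
    ]
    out: list[str] = []
    i = 0
    while i < len(labels):
        folded = False
        for e in events:
            u = len(e.unit)
            if plain[i : i + u] == list(e.unit) and plain[i : i + u * e.n_copies] == list(e.unit) * e.n_copies:
                out.append("(" + " ".join(labels[i : i + u]) + f")x{e.n_copies}")
                i += u * e.n_copies
                folded = True
                break
        if not folded:
            out.append(labels[i])
            i += 1
    return " ".join(out)
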