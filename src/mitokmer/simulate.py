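"""Synthetic circular mitogenomes, heteroplasmic pools, and noisy long reads.

The generator speaks the structural grammar observed in icefish
mitogenomes: a canonical vertebrate gene complement in which the
*ND6*/*trnE*/*trnP*/CR block sits after *trnT* and may be tandemly
duplicated 1-5 times, individual *ND6* copies may carry small frameshift
insertions (1-4 bases), a partially lost extra copy may survive as a
*trnP*/CR remnant, one control region may harbour a tandem repeat, and a
multi-kilobase span may be inverted in place. Gene "sequences" are seeded
random DNA of realistic lengths — structural analysis needs geometry, not
real coding sequence.

Reads emulate PacBio CLR: lengths from a truncated normal (default mean
12 kbp), origins uniform on the circle (reads may cross the origin),
random strand, and i.i.d. per-base errors dominated by indels (defaults
sub 1%, ins 6%, del 4%). Every read comes with a ground-truth row, and
the whole output is bit-reproducible from the seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode, random_dna, revcomp
from .architecture import VERTEBRATE_ORDER

#: Realistic vertebrate gene lengths (nt). ND6 is 528 nt (175 aa + stop).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "trnF": 71, "12S": 950, "trnV": 72, "16S": 1700, "trnL1": 74, "ND1": 975,
    "trnI": 71, "trnQ": 72, "trnM": 69, "ND2": 1045, "trnW": 71, "trnA": 69,
    "trnN": 73, "trnC": 66, "trnY": 70, "COX1": 1550, "trnS1": 71, "trnD": 68,
    "COX2": 690, "trnK": 73, "ATP8": 165, "ATP6": 685, "COX3": 785, "trnG": 68,
    "ND3": 350, "trnR": 68, "ND4L": 295, "ND4": 1380, "trnH": 69, "trnS2": 67,
    "trnL2": 73, "ND5": 1840, "ND6": 528, "trnE": 69, "CYTB": 1140, "trnT": 71,
    "trnP": 69, "CR": 1000,
}

DUP_UNIT = ("ND6", "trnE", "trnP", "CR")

#: Intergenic spacer lengths (nt). The duplicated-unit geometry mirrors the
#: observed one: ~177 nt before each unit copy, ~50 nt between trnE and
#: trnP, 64 nt before a remnant block; consecutive CR copies end up ~900 nt
#: apart so the 800-nt gap rule separates them, as in the real genomes.
DEFAULT_SPACER = 5
UNIT_SPACER = 177       # trnT -> block, and between consecutive unit copies
TRNE_TRNP_SPACER = 50
REMNANT_SPACER = 64     # trnT -> remnant trnP


@dataclass
class ErrorModel:
    """Per-base i.i.d. error probabilities (CLR-like, indel-dominated)."""

    sub_rate: float = 0.01
    ins_rate: float = 0.06
    del_rate: float = 0.04

    def __post_init__(self):
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 0.5:
            raise ValueError("error rates must be >= 0 and sum to < 0.5")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


ERROR_FREE = ErrorModel(0.0, 0.0, 0.0)


@dataclass
class GenomePlan:
    """Declarative description of one mitogenome variant."""

    n_copies: int = 1
    dup_unit: tuple[str, ...] = DUP_UNIT
    truncations: tuple[tuple[int, int, str], ...] = ()  # (copy, offset, bases)
    remnant: Optional[tuple[str, ...]] = None           # e.g. ("trnP", "CR")
    cr_repeat: Optional[tuple[int, float]] = None       # (period, copies)
    inversion: Optional[tuple[str, str]] = None         # (first_gene, last_gene)
    gene_lengths: Optional[dict[str, int]] = None
    seed: int = 17

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        for copy_idx, offset, bases in self.truncations:
            if not 0 <= copy_idx < self.n_copies:
                raise ValueError("truncation copy index out of range")
            if offset < 0 or not bases:
                raise ValueError("bad truncation")
        if self.remnant is not None:
            unit = tuple(self.dup_unit)
            if tuple(self.remnant) not in [unit[i:] for i in range(1, len(unit))]:
                raise ValueError("remnant must be a proper suffix of the unit")
        if self.cr_repeat is not None and self.cr_repeat[1] < 1:
            raise ValueError("cr_repeat copies must be >= 1")


@dataclass
class SimulatedGenome:
    sequence: str
    annotation: pd.DataFrame  # gene, start, end (1-based incl), strand, copy
    plan: GenomePlan
    inversion_span: Optional[int] = None
    label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_intervals(self, gene: str) -> list[tuple[int, int]]:
        """0-based half-open intervals of every copy of ``gene``."""
        rows = self.annotation[self.annotation.gene == gene]
        return [(int(r.start) - 1, int(r.end)) for r in rows.itertuples()]


@dataclass
class HeteroplasmicPool:
    variants: list[SimulatedGenome]
    frequencies: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variants]


def _layout(plan: GenomePlan) -> list[tuple[Optional[str], int, int]]:
    """(label | None=spacer, copy_index, spacer_length_or_0) in order."""
    unit = tuple(plan.dup_unit)
    pre = [g for g in VERTEBRATE_ORDER if g not in unit]
    out: list[tuple[Optional[str], int, int]] = []
    for g in pre:
        out.append((g, 0, 0))
        out.append((None, 0, DEFAULT_SPACER))
    # after trnT: optional remnant, then the unit copies
    out = out[:-1]  # drop the spacer after the final pre gene (trnT)
    if plan.remnant is not None:
        out.append((None, 0, REMNANT_SPACER))
        for j, g in enumerate(plan.remnant):
            if j:
                out.append((None, 0, DEFAULT_SPACER))
            out.append((g, -1, 0))  # copy index -1 marks the remnant
    for c in range(plan.n_copies):
        out.append((None, 0, UNIT_SPACER))
        for j, g in enumerate(unit):
            if j:
                gap = TRNE_TRNP_SPACER if (unit[j - 1], g) == ("trnE", "trnP") \
                    else DEFAULT_SPACER
                out.append((None, 0, gap))
            out.append((g, c, 0))
    return out


def make_genome(plan: GenomePlan, label: str = "") -> SimulatedGenome:
    """Build a circular genome (and its annotation) from a plan.

    Deterministic given ``plan.seed``. The returned annotation uses
    1-based inclusive coordinates and records every gene copy with its
    strand; an applied inversion reverse-complements the planned span in
    place and is reported via ``inversion_span``.
    """
    rng = np.random.default_rng(plan.seed)
    lengths = dict(DEFAULT_GENE_LENGTHS)
    if plan.gene_lengths:
        lengths.update(plan.gene_lengths)
    gene_seqs = {g: random_dna(rng, lengths[g]) for g in VERTEBRATE_ORDER}

    cr_expanded = None
    if plan.cr_repeat is not None:
        period, copies = plan.cr_repeat
        motif = random_dna(rng, period)
        array = (motif * math.ceil(copies + 1))[: round(period * copies)]
        base = gene_seqs["CR"]
        half = len(base) // 2
        cr_expanded = base[:half] + array + base[half:]

    unit = tuple(plan.dup_unit)
    last_copy = plan.n_copies - 1
    truncated = {c: (off, bases) for c, off, bases in plan.truncations}

    segments: list[dict] = []  # label, seq, strand, copy
    for g, copy_idx, spacer_len in _layout(plan):
        if g is None:
            segments.append(
                {"label": None, "seq": random_dna(rng, spacer_len), "strand": "+",
                 "copy_index": 0}
            )
            continue
        seq = gene_seqs[g]
        if g == "CR" and cr_expanded is not None and copy_idx == last_copy:
            seq = cr_expanded
        if g == unit[0] and copy_idx in truncated:
            off, bases = truncated[copy_idx]
            seq = seq[:off] + bases + seq[off:]
        segments.append({"label": g, "seq": seq, "strand": "+", "copy_index": copy_idx})

    inversion_span = None
    if plan.inversion is not None:
        first, last = plan.inversion
        gene_idx = {s["label"]: i for i, s in enumerate(segments) if s["label"]}
        counts = {g: sum(1 for s in segments if s["label"] == g) for g in (first, last)}
        if counts[first] != 1 or counts[last] != 1:
            raise ValueError("inversion endpoints must be unique genes")
        i, j = gene_idx[first], gene_idx[last]
        positions = list(range(i, len(segments))) + list(range(0, j + 1)) \
            if i > j else list(range(i, j + 1))
        block_pos = [
            p for p, s in enumerate(segments)
            if s["label"] in unit and s["copy_index"] >= 0 and s["label"] is not None
        ]
        inside = [p for p in block_pos if p in set(positions)]
        if plan.n_copies >= 2 and inside and len(inside) != len(block_pos):
            raise ValueError("inversion partially overlaps the duplicated unit")
        arc = [segments[p] for p in positions]
        inversion_span = sum(len(s["seq"]) for s in arc)
        arc_rev = [
            {"label": s["label"], "seq": revcomp(s["seq"]),
             "strand": "-" if s["strand"] == "+" else "+", "copy_index": s["copy_index"]}
            for s in reversed(arc)
        ]
        for p, s in zip(positions, arc_rev):
            segments[p] = s

    seq_parts: list[str] = []
    rows = []
    pos = 0
    for s in segments:
        seq_parts.append(s["seq"])
        if s["label"] is not None:
            rows.append(
                {"gene": s["label"], "start": pos + 1, "end": pos + len(s["seq"]),
                 "strand": s["strand"], "copy_index": s["copy_index"]}
            )
        pos += len(s["seq"])
    annotation = pd.DataFrame(rows, columns=["gene", "start", "end", "strand", "copy_index"])
    return SimulatedGenome(
        sequence="".join(seq_parts), annotation=annotation, plan=plan,
        inversion_span=inversion_span, label=label,
    )


def make_pool(variants: Sequence[tuple[GenomePlan, float]]) -> HeteroplasmicPool:
    """Build a heteroplasmic pool; frequencies must sum to 1 (+-1e-9)."""
    freqs = np.array([f for _, f in variants], dtype=float)
    if freqs.size == 0 or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("variant frequencies must be non-negative and sum to 1")
    genomes = [
        make_genome(plan, label=f"variant{i}.copies{plan.n_copies}")
        for i, (plan, _) in enumerate(variants)
    ]
    return HeteroplasmicPool(variants=genomes, frequencies=freqs)


def _apply_errors(codes: np.ndarray, em: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    if em.total == 0:
        return codes
    n = codes.size
    out = codes.copy()
    sub = rng.random(n) < em.sub_rate
    if sub.any():
        out[sub] = (out[sub] + rng.integers(1, 4, int(sub.sum()))) % 4
    keep = rng.random(n) >= em.del_rate
    ins = rng.random(n) < em.ins_rate
    counts = keep.astype(np.int64) + ins
    expanded = np.repeat(out, counts)
    # the last slot of every insertion-carrying base becomes a random base
    # (an insertion on a deleted base degenerates to a substitution)
    cum = np.cumsum(counts)
    slots = cum[ins & (counts > 0)] - 1
    expanded[slots] = rng.integers(0, 4, slots.size)
    return expanded


# thresholds mirroring the default caller: a gene copy is countable when a
# read overlaps it by >= max(ceil(cov*len), k+min_kmers-1) nt (error-free)
def _overlap_needed(gene_len: int, k: int = 19, min_kmers: int = 5,
                    min_cov: float = 0.1) -> int:
    return max(math.ceil(min_cov * gene_len), k + min_kmers - 1)


def _circ_overlap(start: int, length: int, iv: tuple[int, int], G: int) -> int:
    """Overlap of circular read interval [start, start+length) with iv."""
    a, b = iv
    best = 0
    for off in (-G, 0, G):
        lo = max(start, a + off)
        hi = min(start + length, b + off)
        best = max(best, hi - lo)
    return best


def sample_reads(
    pool: HeteroplasmicPool,
    n_reads: int,
    length_distribution: tuple[float, float, float] = (12000.0, 3000.0, 3000.0),
    error_model: ErrorModel = ErrorModel(),
    seed: int = 0,
    anchor_genes: tuple[str, str] = ("12S", "CYTB"),
    counted_gene: str = "ND6",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample noisy long reads from a pool, with per-read ground truth.

    Each read picks a variant by frequency, an origin uniform on the
    circle, a truncated-normal length (capped at the genome length; no
    multi-pass reads), a random strand, and then per-base errors. The
    truth table records the variant, the number of ``counted_gene``
    copies the error-free read interval overlaps enough to count, and
    whether it spans both anchors (same overlap rule), all relative to
    the error-free source interval.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    mean, sd, min_len = length_distribution
    rng = np.random.default_rng(seed)
    variant_idx = rng.choice(len(pool.variants), size=n_reads, p=pool.frequencies)

    encoded = [encode(v.sequence.upper()) for v in pool.variants]
    doubled = [np.concatenate([e, e]) for e in encoded]
    anchor_ivs = [
        {g: v.gene_intervals(g)[0] for g in anchor_genes} for v in pool.variants
    ]
    gene_ivs = [v.gene_intervals(counted_gene) for v in pool.variants]
    # the arc a read must contain to span the anchors via the duplicated
    # side: from (right-anchor end - needed overlap), through the block and
    # across the origin, to (left-anchor start + needed overlap)
    dup_arcs = []
    for v, ivs in zip(pool.variants, anchor_ivs):
        G = len(v)
        (l_a, l_b) = ivs[anchor_genes[0]]
        (r_a, r_b) = ivs[anchor_genes[1]]
        a_start = (r_b - _overlap_needed(r_b - r_a)) % G
        arc_len = (l_a + _overlap_needed(l_b - l_a) - a_start) % G
        dup_arcs.append((a_start, arc_len))

    reads: list[tuple[str, str]] = []
    rows = []
    for i in range(n_reads):
        vi = int(variant_idx[i])
        G = encoded[vi].size
        length = 0
        while length < min_len:
            length = int(round(rng.normal(mean, sd)))
        length = min(length, G)
        origin = int(rng.integers(0, G))
        raw = doubled[vi][origin : origin + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = 3 - raw[::-1]
        final = _apply_errors(raw, error_model, rng)
        read_id = f"read_{i:05d}"
        reads.append((read_id, decode(final)))

        n_copies = sum(
            1
            for iv in gene_ivs[vi]
            if _circ_overlap(origin, length, iv, G)
            >= _overlap_needed(iv[1] - iv[0])
        )
        spans = all(
            _circ_overlap(origin, length, iv, G) >= _overlap_needed(iv[1] - iv[0])
            for iv in anchor_ivs[vi].values()
        )
        a_start, arc_len = dup_arcs[vi]
        via_dup = ((a_start - origin) % G) + arc_len <= length
        rows.append(
            {"read_id": read_id, "source_variant": pool.variants[vi].label,
             "true_copy_count": n_copies, "spans_anchors": spans,
             "spans_duplicated_side": via_dup,
             "origin": origin, "length": length, "strand": strand}
        )
    truth = pd.DataFrame(rows)
    return reads, truth


def expected_class_probabilities(
    pool: HeteroplasmicPool,
    length_distribution: tuple[float, float, float] = (12000.0, 3000.0, 3000.0),
    anchor_genes: tuple[str, str] = ("12S", "CYTB"),
    counted_gene: str = "ND6",
    n_length_bins: int = 400,
) -> dict[int, float]:
    """Exact class probabilities among duplicated-side spanning reads.

    Variants differ in genome length G and in the arc a read must contain
    to span both anchors through the duplicated side, so spanning reads
    are *not* drawn from the raw pool frequencies: variant v contributes
    in proportion to f_v * E[max(0, min(L, G_v) - arc_v)] / G_v under the
    truncated-normal read-length law (numeric quadrature). A read
    containing the whole arc carries every copy of the counted gene, so
    each variant maps to a single class.
    """
    mean, sd, min_len = length_distribution
    xs = np.linspace(min_len, mean + 8 * sd, n_length_bins)
    pdf = np.exp(-0.5 * ((xs - mean) / sd) ** 2)
    weights = pdf / pdf.sum()

    raw: dict[int, float] = {}
    for v, f in zip(pool.variants, pool.frequencies):
        G = len(v)
        (l_a, l_b) = v.gene_intervals(anchor_genes[0])[0]
        (r_a, r_b) = v.gene_intervals(anchor_genes[1])[0]
        a_start = (r_b - _overlap_needed(r_b - r_a)) % G
        arc = (l_a + _overlap_needed(l_b - l_a) - a_start) % G
        p_span = float(
            np.sum(weights * np.maximum(0.0, np.minimum(xs, G) - arc)) / G
        )
        n_cop = len(v.gene_intervals(counted_gene))
        raw[n_cop] = raw.get(n_cop, 0.0) + f * p_span
    total = sum(raw.values())
    return {c: p / total for c, p in sorted(raw.items())}


# ---------------------------------------------------------------------------
# Presets: the structural variants and pools observed in the five species
# ---------------------------------------------------------------------------

def esox_pool(seed: int = 17) -> HeteroplasmicPool:
    """4/3/1/5-copy variants at frequencies 0.70/0.23/0.04/0.03.

    The proportions mirror the observed spanning-read spectrum 33/11/2/1
    (of 47 copy-carrying reads); the 4-copy variant carries one
    frameshifted (single-base insertion) *ND6* copy.
    """
    base = GenomePlan(seed=seed)
    return make_pool([
        (replace(base, n_copies=4, truncations=((1, 241, "G"),)), 33 / 47),
        (replace(base, n_copies=3), 11 / 47),
        (replace(base, n_copies=1), 2 / 47),
        (replace(base, n_copies=5), 1 / 47),
    ])


def aceratus_pool(seed: int = 17) -> HeteroplasmicPool:
    """2/3/1/4-copy variants at the observed 304/193/6/1 proportions."""
    base = GenomePlan(seed=seed)
    return make_pool([
        (replace(base, n_copies=2), 304 / 504),
        (replace(base, n_copies=3), 193 / 504),
        (replace(base, n_copies=1), 6 / 504),
        (replace(base, n_copies=4), 1 / 504),
    ])


def gunnari_plan(seed: int = 17) -> GenomePlan:
    """Four unit copies, two with frameshift insertions (3 Gs / 4 Gs)."""
    return GenomePlan(
        n_copies=4, truncations=((1, 241, "GGG"), (2, 241, "GGGG")), seed=seed
    )


def georgianus_plan(seed: int = 17) -> GenomePlan:
    """Two unit copies plus a trnP/CR remnant; 53-bp repeat x8.8 in a CR."""
    return GenomePlan(
        n_copies=2, remnant=("trnP", "CR"), cr_repeat=(53, 8.8), seed=seed
    )


def borchgrevinki_plan(seed: int = 17) -> GenomePlan:
    """Single unit copy; expanded repeat-bearing CR inside a ~6.5-kbp
    inversion running from the CR through *trnI* across the origin."""
    return GenomePlan(
        n_copies=1, cr_repeat=(97, 8.0), inversion=("CR", "trnI"), seed=seed
    )


PRESET_PLANS = {
    "canonical": lambda seed=17: GenomePlan(seed=seed),
    "gunnari": gunnari_plan,
    "georgianus": georgianus_plan,
    "borchgrevinki": borchgrevinki_plan,
}
PRESET_POOLS = {"esox": esox_pool, "aceratus": aceratus_pool}
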