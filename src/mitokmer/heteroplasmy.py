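"""Copy-number spectra and heteroplasmy calls.

A *copy-number spectrum* is the histogram of per-read gene copy counts
over the reads spanning the duplicated region's anchors. A multimodal
spectrum — several copy-number classes each supported by multiple reads —
is direct evidence of structural heteroplasmy: mitogenome variants with
different numbers of the duplicated block co-occurring in one individual.

Reads with a copy count of zero are kept as class 0 rather than dropped:
complete loss of the duplicated gene from a block is biologically real
(remnant blocks), and anchor-spanning reads covering the opposite side of
the circle legitimately carry no copy.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .kmer import CopyCall


@dataclass
class CopySpectrum:
    """Histogram of copy counts over anchor-spanning reads."""

    counts: dict[int, int]
    n_spanning: int
    label: str = ""

    def __post_init__(self):
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("negative class count")
        if sum(self.counts.values()) > self.n_spanning:
            raise ValueError("class counts exceed number of spanning reads")

    @property
    def modal_class(self) -> int | None:
        """Most supported copy number among classes >= 1 copy."""
        nonzero = {c: n for c, n in self.counts.items() if c >= 1}
        if not nonzero:
            return None
        return max(nonzero, key=lambda c: (nonzero[c], -c))


@dataclass
class HeteroplasmyCall:
    is_heteroplasmic: bool
    supported_classes: list[tuple[int, int, str]]  # (copy_number, n_reads, flag)
    min_support: int


def build_spectrum(
    calls: Iterable[CopyCall],
    spanning_ids: set[str] | Sequence[str],
    label: str = "",
) -> CopySpectrum:
    """Count copy classes over the reads in ``spanning_ids``.

    ``n_spanning`` is the total number of anchor-spanning reads, which may
    exceed the number with a copy call; classes with zero reads are omitted.
    """
    spanning = set(spanning_ids)
    counter: Counter[int] = Counter(
        call.copy_count for call in calls if call.read_id in spanning
    )
    return CopySpectrum(counts=dict(sorted(counter.items())),
                        n_spanning=len(spanning), label=label)


def call_heteroplasmy(spectrum: CopySpectrum, min_support: int = 2) -> HeteroplasmyCall:
    """Binary heteroplasmy verdict from a spectrum.

    Heteroplasmic iff at least two copy-number classes reach
    ``min_support`` reads. Classes below the support threshold are still
    reported, flagged 'singleton' — a one-read class (e.g. a 5-copy read)
    is worth reporting even when it cannot carry the verdict alone.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    supported = [
        (c, n, "confident" if n >= min_support else "singleton")
        for c, n in sorted(spectrum.counts.items())
    ]
    n_confident = sum(1 for _, n, _ in supported if n >= min_support)
    return HeteroplasmyCall(
        is_heteroplasmic=n_confident >= 2,
        supported_classes=supported,
        min_support=min_support,
    )


def partition_reads(calls: Iterable[CopyCall]) -> dict[int, list[str]]:
    """Group read ids by copy count, for per-variant assembly export.

    Every called read appears in exactly one class.
    """
    out: dict[int, list[str]] = {}
    for call in calls:
        out.setdefault(call.copy_count, []).append(call.read_id)
    return dict(sorted(out.items()))
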