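"""Tandem repeat detection in control regions.

Mitochondrial control regions vary in length largely through tandem
repeats (periods of tens to hundreds of nucleotides, often a fractional
number of copies). This module detects them with a lag-correlation scan:

1. *seed*: for every candidate period d, count exact seed k-mer
   self-matches at lag d (k = min(7, min_period)); lags without enough
   seeds are skipped.
2. *extend*: per surviving lag, compare the sequence with itself shifted
   by d and locate dense runs of per-base matches (rolling identity over
   a window >= the identity threshold).
3. *refine*: within each candidate region, the period is the smallest lag
   whose mean adjacent-window identity is within a small tolerance (0.01)
   of the best over all lags — this returns the fundamental period rather
   than one of its harmonics, and stays stable under point mutations.
4. *trim*: region boundaries are anchored on short runs of consecutive
   matching positions at the final period, so chance matches in the
   flanking sequence do not inflate the fractional copy number.
5. *report*: copies = region_length / period rounded to one decimal (the
   conventional fractional-copy report, e.g. "53 bp repeated 8.8 times");
   consensus = per-column majority over period-phased windows.

Coordinates are 0-based half-open internally; 1-based inclusive in TSV
reports.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import decode, encode, kmer_codes


@dataclass(frozen=True)
class TandemRepeat:
    start: int
    end: int
    period: int
    copies: float
    consensus: str
    identity: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _lag_matches(arr: np.ndarray, valid: np.ndarray, d: int) -> np.ndarray:
    return (arr[:-d] == arr[d:]) & valid[:-d] & valid[d:]


def _refine_region(
    arr: np.ndarray,
    valid: np.ndarray,
    s: int,
    e: int,
    min_period: int,
    max_period: int,
    min_copies: float,
    min_identity: float,
    tie_tolerance: float = 0.01,
) -> TandemRepeat | None:
    seg = arr[s:e]
    vseg = valid[s:e]
    region_len = e - s
    lag_hi = min(max_period, region_len - 1)
    identities: dict[int, float] = {}
    for d in range(min_period, lag_hi + 1):
        m = _lag_matches(seg, vseg, d)
        # too few comparisons make identity meaningless (e.g. a lag just
        # below the region length always matches the leading bases)
        if m.size < max(8, int(0.5 * d)):
            continue
        identities[d] = float(m.mean())
    if not identities:
        return None
    # period selection happens before boundary trimming, so identities are
    # diluted by whatever flank the candidate region drags in; the ranking
    # across lags is preserved and the trimmed segment is re-gated below
    best = max(identities.values())
    period = min(d for d, idv in identities.items() if idv >= best - tie_tolerance)

    # trim boundaries to the maximum-scoring segment of the match profile
    # (match +1, mismatch -3): the repeat body scores upward while the
    # random flank (~25% matches) drifts at -2/position, so candidate
    # overshoot into the flanks is clipped to at most a couple of chance
    # matches at each edge
    m = _lag_matches(seg, vseg, period)
    if m.size == 0:
        return None
    x = np.where(m, 1.0, -3.0)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    minpos = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - minpos
    te = int(np.argmax(gains))
    if gains[te] <= 0:
        return None
    ts = int(np.argmin(prefix[: te + 1]))  # segment is (ts, te] in prefix space
    # snap edges to clean runs of `ar` matches: short chance extensions
    # (even ones containing a lucky 4-5 match run) survive Kadane but not
    # this (P(6 random matches in a row) = 4^-6 ~ 2e-4)
    ar = min(period, 6)
    seg_m = m[ts : te + 1]
    if seg_m.size < ar:
        return None
    runs = np.convolve(seg_m.astype(np.int32), np.ones(ar, np.int32), "valid")
    clean = np.nonzero(runs == ar)[0]
    if clean.size == 0:
        return None
    te = ts + int(clean[-1]) + ar - 1
    ts = ts + int(clean[0])
    start, end = s + ts, s + te + 1 + period
    copies = round((end - start) / period, 1)
    if copies < min_copies:
        return None
    identity = float(m[ts : te + 1].mean())
    if identity < min_identity:
        return None

    # consensus: column majority over period-phased full windows
    n_win = (end - start) // period
    windows = arr[start : start + n_win * period].reshape(n_win, period)
    consensus_codes = np.empty(period, np.uint8)
    for j in range(period):
        col = windows[:, j]
        col = col[col < 4]
        if col.size == 0:
            consensus_codes[j] = 0
        else:
            consensus_codes[j] = np.bincount(col, minlength=4).argmax()
    return TandemRepeat(
        start=start,
        end=end,
        period=period,
        copies=copies,
        consensus=decode(consensus_codes),
        identity=identity,
    )


def find_tandem_repeats(
    seq: str,
    min_period: int = 10,
    max_period: int = 400,
    min_copies: float = 1.9,
    min_identity: float = 0.8,
    min_seed_matches: int = 3,
) -> list[TandemRepeat]:
    """Detect tandem repeats in ``seq``; see the module docstring.

    Defaults cover the repeat geometries typical of fish control regions
    (periods ~50-300 nt). Returns repeats sorted by start position; an
    empty sequence yields an empty list.
    """
    if not 1 <= min_period <= max_period:
        raise ValueError("need 1 <= min_period <= max_period")
    L = len(seq)
    if L < 2 * min_period:
        return []
    arr = encode(seq)
    valid = arr < 4
    k_seed = min(7, min_period)
    seed_codes, seed_valid = kmer_codes(arr, k_seed)

    candidates: list[tuple[int, int]] = []
    lag_hi = min(max_period, L - k_seed - 1, int(L / max(min_copies, 1.0)))
    for d in range(min_period, lag_hi + 1):
        sm = (seed_codes[:-d] == seed_codes[d:]) & seed_valid[:-d] & seed_valid[d:]
        if int(sm.sum()) < min_seed_matches:
            continue
        m = _lag_matches(arr, valid, d)
        w = min(d, 20)
        roll = np.convolve(m.astype(np.int32), np.ones(w, np.int32), "valid")
        good = roll >= min_identity * w - 1e-9
        for a, b in _merge_runs(_bool_runs(good), max_gap=w):
            mend = b - 1 + w  # end of the dense match span in lag-match space
            s_reg, e_reg = a, mend + d
            if (e_reg - s_reg) / d < min_copies - 0.05:
                continue
            if int(sm[a : max(a + 1, mend - k_seed + 1)].sum()) < 2:
                continue
            candidates.append((s_reg, e_reg))
    if not candidates:
        return []

    # union-merge overlapping candidate regions (harmonic lags of the same
    # repeat produce near-identical regions); refinement rescans all lags
    candidates.sort()
    regions: list[list[int]] = []
    for s_reg, e_reg in candidates:
        if regions and s_reg < regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], e_reg)
        else:
            regions.append([s_reg, e_reg])

    repeats: list[TandemRepeat] = []
    for s_reg, e_reg in regions:
        rep = _refine_region(
            arr, valid, s_reg, e_reg, min_period, max_period, min_copies, min_identity
        )
        if rep is not None:
            repeats.append(rep)

    # harmonic suppression between surviving repeats
    def contained(r: TandemRepeat, q: TandemRepeat, slack: int = 5) -> bool:
        return q.start - slack <= r.start and r.end <= q.end + slack

    kept: list[TandemRepeat] = []
    for r in repeats:
        drop = False
        for q in repeats:
            if q is r or not contained(r, q):
                continue
            if r.period > q.period and r.period % q.period == 0 and r.identity <= q.identity:
                drop = True  # harmonic duplicate of a stronger fundamental
            if r.period < q.period and q.period % r.period == 0 and r.identity < q.identity:
                drop = True  # weaker sub-harmonic inside a stronger container
        if not drop:
            kept.append(r)
    kept.sort(key=lambda r: (r.start, r.period))
    return kept
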