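"""Low-level nucleotide utilities shared across modules.

Sequences are plain Python strings; hot loops work on 2-bit numpy codes
(A=0, C=1, G=2, T=3; anything else = 4, treated as ambiguous).
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes (ambiguous bases -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for every k-mer of an encoded sequence.

    Returns (codes, valid); ``codes[i]`` is the base-4 integer of
    ``arr[i:i+k]`` and ``valid[i]`` is False when the window contains an
    ambiguous base (its code is then meaningless). k must be <= 31 so the
    code fits in a signed 64-bit integer.
    """
    if k < 1 or k > 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = arr.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    # ambiguous code 4 would alias; mask first, clip for the dot product
    valid = ~(win == 4).any(axis=1)
    codes = np.minimum(win, 3).astype(np.int64) @ powers
    return codes, valid


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))
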