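"""Shared low-level helpers: 2-bit base codes, interval arithmetic, seeded RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

# ASCII <-> 2-bit code tables. Code 4 marks any non-ACGT character.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i
_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq) -> np.ndarray:
    """Sequence (str/bytes/uint8 codes) -> uint8 array of 2-bit codes (4 = non-ACGT)."""
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8 and seq.size and seq.max() <= 4:
            return seq
        seq = seq.tobytes()
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = (3 - codes[::-1]).astype(np.uint8)
    out[codes[::-1] == 4] = 4
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by (seed, tags).

    String tags are hashed with crc32 so streams for different generator stages
    never collide or depend on call order.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        ints.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Collapse possibly-overlapping half-open intervals into a sorted disjoint set."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def covered_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def jaccard(set_a, set_b) -> float:
    """Jaccard index between two interval sets (half-open, same chromosome)."""
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    inter = 0
    for ia in a:
        for ib in b:
            inter += interval_overlap(ia, ib)
    union = covered_length(list(a) + list(b))
    return inter / union if union else float("nan")
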