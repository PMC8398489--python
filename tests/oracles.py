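"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's index/convolution code paths:
mapping is an all-position, both-strand scan; the ping-pong pair weight is
an O(n^2) enumeration over read pairs.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def brute_force_map(read: str, segments: dict[str, str], *,
                    max_mismatches: int = 2, min_identity: float = 0.9,
                    min_read_len: int = 18):
    """All accepted full-length placements as (mismatches, seg, start, strand)."""
    read = read.upper()
    L = len(read)
    if L <= min_read_len:
        return []
    hits = []
    for strand, query in (("+", read), ("-", revcomp(read))):
        q = _codes(query)
        for seg_id, seg in segments.items():
            s = _codes(seg.upper())
            if len(s) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(s, L)
            mism = ((windows != q) | (windows == 4) | (q == 4)).sum(axis=1)
            for start in np.flatnonzero(
                    (mism <= max_mismatches) & ((L - mism) / L >= min_identity)):
                hits.append((int(mism[start]), seg_id, int(start), strand))
    return hits


def brute_force_best_unique(read: str, segments: dict[str, str], **kw):
    hits = brute_force_map(read, segments, **kw)
    if not hits:
        return None
    best = min(h[0] for h in hits)
    return sorted(h for h in hits if h[0] == best)[0]


def allpairs_pair_weight(alignments, window=(24, 29), o_range=(1, 29)):
    """O(n^2) enumeration: count (sense, antisense) pairs per 5'-overlap."""
    lo, hi = window
    sense, anti = [], []
    for a in alignments:
        length = a.end - a.start
        if not lo <= length <= hi:
            continue
        p5 = a.start if a.strand == "+" else a.end - 1
        (sense if a.strand == "+" else anti).append((a.segment_id, p5))
    o_lo, o_hi = o_range
    weights = np.zeros(o_hi - o_lo + 1)
    for seg_s, i in sense:
        for seg_a, j in anti:
            if seg_s != seg_a:
                continue
            o = j - i + 1
            if o_lo <= o <= o_hi:
                weights[o - o_lo] += 1
    return weights
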