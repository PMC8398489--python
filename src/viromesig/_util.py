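"""Shared low-level helpers: nucleotide encoding, reverse complement, seeding."""
from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; anything else (incl. N) -> 4, which never matches.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (N and unknowns -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a global seed by hashing."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal-style half-up rounding (Python's round() is banker's)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
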