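"""A minimal strand-aware ungapped small-RNA mapper.

Reads of 18-32 nt are placed full-length on reference segments, both
strands, under identity and coverage thresholds (defaults 0.9/0.9, reads
must exceed 18 nt).  Candidate placements come from an exact k-mer seed
index; with the default seed size the seeded search is exhaustive for the
default mismatch budget (pigeonhole: a read of length L with m mismatches
contains an exact run of at least ceil((L - m)/(m + 1)) matching bases),
so results coincide with a brute-force all-position scan.

Indels are out of model: at these read lengths the mappers used for this
kind of screening operate effectively ungapped.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqRecord import SeqRecord

from ._util import encode_seq, revcomp

_REPORT_POLICIES = ("best-unique", "best-random-tie", "all-best")


@dataclass(frozen=True)
class AlignmentParams:
    """Mapping contract: length, mismatch, identity and coverage thresholds."""

    min_read_len: int = 18          # exclusive lower bound
    max_mismatches: int = 2
    min_aligned_fraction: float = 0.9
    min_identity: float = 0.9
    seed_k: int = 6
    report: str = "best-unique"
    seed: int | None = None         # RNG seed for best-random-tie

    def __post_init__(self):
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")
        if not 0.0 < self.min_aligned_fraction <= 1.0:
            raise ValueError("min_aligned_fraction must lie in (0, 1]")
        if self.seed_k > self.min_read_len:
            raise ValueError("seed_k must not exceed min_read_len")
        if self.seed_k < 1:
            raise ValueError("seed_k must be positive")
        if self.report not in _REPORT_POLICIES:
            raise ValueError(f"report must be one of {_REPORT_POLICIES}")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placed on one segment; 0-based half-open coordinates."""

    read_id: str
    segment_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    identity: float
    aligned_fraction: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")


@dataclass
class MappingSummary:
    n_input: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_skipped_short: int = 0

    def conserved(self) -> bool:
        return self.n_input == self.n_mapped + self.n_unmapped + self.n_skipped_short


class KmerIndex:
    """Exact k-mer -> (segment, position) index over the sense strand."""

    def __init__(self, segments: Sequence[SeqRecord], k: int = 6):
        if not segments:
            raise ValueError("segments must be non-empty")
        self.k = int(k)
        self.segment_ids: list[str] = []
        self.encoded: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {}
        self._index: dict[bytes, list[tuple[str, int]]] = {}
        for rec in segments:
            seq = str(rec.seq).upper()
            if len(seq) < self.k:
                raise ValueError(f"segment {rec.id} shorter than k={self.k}")
            self.segment_ids.append(rec.id)
            enc = encode_seq(seq)
            self.encoded[rec.id] = enc
            self.lengths[rec.id] = len(seq)
            for pos in range(len(seq) - self.k + 1):
                kmer = enc[pos:pos + self.k]
                if (kmer == 4).any():    # k-mers containing N are unmatchable
                    continue
                self._index.setdefault(kmer.tobytes(), []).append((rec.id, pos))

    def lookup(self, kmer: str | np.ndarray) -> list[tuple[str, int]]:
        enc = encode_seq(kmer) if isinstance(kmer, str) else kmer
        if len(enc) != self.k:
            raise ValueError(f"query length must equal k={self.k}")
        return self._index.get(enc.tobytes(), [])


def build_index(segments: Sequence[SeqRecord], k: int = 6) -> KmerIndex:
    return KmerIndex(segments, k=k)


def _candidate_starts(enc_query: np.ndarray, index: KmerIndex) -> set[tuple[str, int]]:
    k = index.k
    out: set[tuple[str, int]] = set()
    for offset in range(len(enc_query) - k + 1):
        kmer = enc_query[offset:offset + k]
        if (kmer == 4).any():
            continue
        for seg_id, pos in index._index.get(kmer.tobytes(), []):
            out.add((seg_id, pos - offset))
    return out


def map_read(read_id: str, seq: str, index: KmerIndex,
             params: AlignmentParams = AlignmentParams(),
             rng: np.random.Generator | None = None) -> list[AlignmentRecord]:
    """Place one read; returns records per the configured report policy."""
    seq = seq.upper()
    L = len(seq)
    if L <= params.min_read_len:
        return []
    hits: list[tuple[int, str, int, str]] = []  # (mismatches, seg, start, strand)
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        enc_q = encode_seq(query)
        for seg_id, start in _candidate_starts(enc_q, index):
            if start < 0 or start + L > index.lengths[seg_id]:
                continue
            window = index.encoded[seg_id][start:start + L]
            mism = int(np.count_nonzero(
                (window != enc_q) | (window == 4) | (enc_q == 4)))
            identity = (L - mism) / L
            if mism <= params.max_mismatches and identity >= params.min_identity:
                hits.append((mism, seg_id, start, strand))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    best_hits = sorted(h for h in hits if h[0] == best)  # (seg, start, strand) lexicographic
    if params.report == "all-best":
        chosen = best_hits
    elif params.report == "best-random-tie":
        rng = rng or np.random.default_rng(params.seed)
        chosen = [best_hits[rng.integers(len(best_hits))]]
    else:
        chosen = [best_hits[0]]
    return [AlignmentRecord(read_id=read_id, segment_id=seg, strand=strand,
                            start=start, end=start + L, mismatches=mism,
                            identity=(L - mism) / L, aligned_fraction=1.0)
            for mism, seg, start, strand in chosen]


def map_library(reads: Iterable[SeqRecord] | Mapping[str, str],
                index: KmerIndex,
                params: AlignmentParams = AlignmentParams(),
                *, allow_empty: bool = False
                ) -> tuple[list[AlignmentRecord], MappingSummary]:
    """Map a library; summary counts satisfy
    n_input = n_mapped + n_unmapped + n_skipped_short."""
    if isinstance(reads, Mapping):
        items = list(reads.items())
    else:
        items = [(rec.id, str(rec.seq)) for rec in reads]
    if not items and not allow_empty:
        raise ValueError("empty read set; pass allow_empty=True")
    rng = np.random.default_rng(params.seed) if params.report == "best-random-tie" else None
    summary = MappingSummary(n_input=len(items))
    alignments: list[AlignmentRecord] = []
    for read_id, seq in items:
        if len(seq) <= params.min_read_len:
            summary.n_skipped_short += 1
            continue
        recs = map_read(read_id, seq, index, params, rng=rng)
        if recs:
            summary.n_mapped += 1
            alignments.extend(recs)
        else:
            summary.n_unmapped += 1
    return alignments, summary
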