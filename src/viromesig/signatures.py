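"""Strand-resolved small-RNA signature battery and RNAi-status classification.

Given read-to-genome alignments for one virus-library pair, this module
computes:

* the read-length distribution per strand (18-32 nt);
* per-strand 5'-end coverage (the 5' end of an antisense read is the
  rightmost genomic coordinate of its interval);
* positional nucleotide frequencies over read positions 1..10, in each
  read's own 5'->3' orientation, restricted to a piRNA-sized length
  window (default 24-29 nt) -- the U1/A10 ping-pong hallmark;
* the 5'-overlap ping-pong signature: pair_weight[o] = sum_i f+(i) *
  f-(i + o - 1) over genomic positions i, for overlaps o = 1..29, with
  z-scores standardised across the overlap range.  A perfect ping-pong
  pair overlaps by exactly o = 10 terminal nucleotides;

and classifies the pair as actively replicating (vsiRNA response on both
strands), ping-pong vpiRNA producing, both, endogenised-element-like
(single-orientation piRNAs with no vsiRNA peak), undetected, or ambiguous.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp

LEN_RANGE = range(18, 33)
STRANDS = ("+", "-")
DEFAULT_WINDOW = (24, 29)
_BASE_ORDER = ("A", "C", "G", "T")


def _pos5(aln) -> int:
    return aln.start if aln.strand == "+" else aln.end - 1


# ------------------------------------------------------------- size profile

@dataclass
class SizeProfile:
    """Read counts by (length 18..32, strand)."""

    counts: pd.DataFrame  # index: lengths 18..32; columns: '+', '-'

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def window_counts(self, window: tuple[int, int] = DEFAULT_WINDOW) -> pd.Series:
        lo, hi = window
        return self.counts.loc[lo:hi].sum(axis=0)

    def length_fraction(self, length: int) -> float:
        if self.total == 0:
            return 0.0
        return float(self.counts.loc[length].sum()) / self.total


def size_distribution(alignments: Sequence) -> SizeProfile:
    counts = pd.DataFrame(0, index=list(LEN_RANGE), columns=list(STRANDS))
    for aln in alignments:
        length = aln.end - aln.start
        if length in counts.index:
            counts.loc[length, aln.strand] += 1
    return SizeProfile(counts=counts)


# ---------------------------------------------------------- 5'-end coverage

@dataclass
class StrandedCoverage:
    """Per-strand histograms of read 5' ends along one segment."""

    segment_id: str
    plus: np.ndarray
    minus: np.ndarray

    def strand_total(self, strand: str) -> int:
        return int((self.plus if strand == "+" else self.minus).sum())

    @property
    def breadth(self) -> float:
        covered = (self.plus + self.minus) > 0
        return float(covered.mean())


def coverage_5prime(alignments: Sequence, segment_id: str,
                    segment_length: int) -> StrandedCoverage:
    plus = np.zeros(segment_length, dtype=np.int64)
    minus = np.zeros(segment_length, dtype=np.int64)
    for aln in alignments:
        if aln.segment_id != segment_id:
            continue
        if aln.start < 0 or aln.end > segment_length:
            raise ValueError(
                f"alignment {aln.read_id} [{aln.start},{aln.end}) exceeds "
                f"segment {segment_id} bounds (length {segment_length})")
        p5 = _pos5(aln)
        (plus if aln.strand == "+" else minus)[p5] += 1
    return StrandedCoverage(segment_id=segment_id, plus=plus, minus=minus)


# ------------------------------------------------------- positional biases

@dataclass
class PositionBias:
    """Nucleotide frequencies at read positions 1..10 per orientation.

    Frequencies are taken on each read's own 5'->3' sequence; ``defined``
    flags orientations with at least one read in the length window.
    """

    sense: pd.DataFrame      # rows A/C/G/T, columns 1..10
    antisense: pd.DataFrame
    n_sense: int
    n_antisense: int
    window: tuple[int, int]

    def defined(self, orientation: str) -> bool:
        return (self.n_sense if orientation == "sense" else self.n_antisense) > 0

    def frequency(self, orientation: str, base: str, position: int) -> float:
        frame = self.sense if orientation == "sense" else self.antisense
        return float(frame.loc[base, position])


def nucleotide_bias(alignments: Sequence, read_seqs: Mapping[str, str],
                    window: tuple[int, int] = DEFAULT_WINDOW) -> PositionBias:
    """Positional base frequencies of windowed reads, split by strand.

    ``read_seqs`` maps read id to the read's own (as-sequenced) 5'->3'
    sequence; an antisense read is therefore already the reverse
    complement of its genomic interval.
    """
    lo, hi = window
    counts = {s: np.zeros((4, 10), dtype=np.int64) for s in STRANDS}
    n = {s: 0 for s in STRANDS}
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}
    for aln in alignments:
        length = aln.end - aln.start
        if not lo <= length <= hi:
            continue
        seq = read_seqs[aln.read_id].upper()
        n[aln.strand] += 1
        for pos in range(min(10, len(seq))):
            i = base_idx.get(seq[pos])
            if i is not None:
                counts[aln.strand][i, pos] += 1
    frames = {}
    for strand in STRANDS:
        c = counts[strand].astype(float)
        totals = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(totals > 0, c / totals, np.nan)
        frames[strand] = pd.DataFrame(f, index=list(_BASE_ORDER),
                                      columns=list(range(1, 11)))
    return PositionBias(sense=frames["+"], antisense=frames["-"],
                        n_sense=n["+"], n_antisense=n["-"], window=(lo, hi))


# ------------------------------------------------------ ping-pong signature

@dataclass
class OverlapSignature:
    """5'-overlap pair weights and z-scores over overlaps 1..29."""

    overlaps: np.ndarray
    pair_weight: np.ndarray
    zscore: np.ndarray
    window: tuple[int, int]
    n_sense: int
    n_antisense: int
    defined: bool = True     # False when <2 windowed reads on opposite strands
    degenerate: bool = False  # True when sd of pair weights is 0

    def z(self, overlap: int) -> float:
        return float(self.zscore[int(np.flatnonzero(self.overlaps == overlap)[0])])

    @property
    def argmax_overlap(self) -> int:
        return int(self.overlaps[int(np.argmax(self.pair_weight))])


def pingpong_signature(alignments: Sequence,
                       window: tuple[int, int] = DEFAULT_WINDOW,
                       o_range: tuple[int, int] = (1, 29)) -> OverlapSignature:
    """Ping-pong overlap statistic from 5'-end count histograms.

    pair_weight[o] multiplies sense 5'-end counts at genomic position i
    with antisense 5'-end counts at i + o - 1 and sums over i and over
    segments; z-scores standardise across the overlap range (zero spread
    flags the signature degenerate).
    """
    lo, hi = window
    o_lo, o_hi = o_range
    overlaps = np.arange(o_lo, o_hi + 1)
    per_segment: dict[str, dict[str, list[int]]] = {}
    n = {"+": 0, "-": 0}
    for aln in alignments:
        length = aln.end - aln.start
        if not lo <= length <= hi:
            continue
        n[aln.strand] += 1
        per_segment.setdefault(aln.segment_id, {"+": [], "-": []})[
            aln.strand].append(_pos5(aln))
    if n["+"] < 1 or n["-"] < 1 or n["+"] + n["-"] < 2:
        nan = np.full(overlaps.shape, np.nan)
        return OverlapSignature(overlaps=overlaps, pair_weight=nan.copy(),
                                zscore=nan, window=(lo, hi), n_sense=n["+"],
                                n_antisense=n["-"], defined=False)
    weight = np.zeros(overlaps.shape, dtype=float)
    for positions in per_segment.values():
        if not positions["+"] or not positions["-"]:
            continue
        top = max(max(positions["+"]), max(positions["-"])) + 1
        fplus = np.bincount(positions["+"], minlength=top).astype(float)
        fminus = np.bincount(positions["-"], minlength=top).astype(float)
        for j, o in enumerate(overlaps):
            d = o - 1
            if d >= top:
                continue
            weight[j] += float(np.dot(fplus[:top - d], fminus[d:]))
    sd = float(weight.std())
    if sd == 0.0:
        return OverlapSignature(overlaps=overlaps, pair_weight=weight,
                                zscore=np.zeros_like(weight), window=(lo, hi),
                                n_sense=n["+"], n_antisense=n["-"],
                                degenerate=True)
    z = (weight - weight.mean()) / sd
    return OverlapSignature(overlaps=overlaps, pair_weight=weight, zscore=z,
                            window=(lo, hi), n_sense=n["+"], n_antisense=n["-"])


# ------------------------------------------------------------ classification

@dataclass(frozen=True)
class RnaiThresholds:
    """Decision thresholds for the RNAi status call (all configurable)."""

    n_min: int = 100                 # minimum mapped reads for any call
    sirna_peak_fraction: float = 0.15   # 21-nt reads / all 18-32 nt reads
    sirna_minority_share: float = 0.10  # minority-strand share of 21-nt reads
    s_eve: float = 0.95              # single-orientation fraction, piRNA window
    z_min: float = 3.29              # ping-pong z at overlap 10
    min_u1: float = 0.5              # antisense position-1 U frequency
    min_a10: float = 0.5             # sense position-10 A frequency
    window: tuple[int, int] = DEFAULT_WINDOW


STATUSES = ("ACTIVE_SIRNA", "PIRNA_PINGPONG", "ACTIVE_SIRNA_PLUS_PIRNA",
            "EVE_LIKE", "NOT_DETECTED", "AMBIGUOUS")


@dataclass
class RnaiCall:
    status: str
    evidence: dict = field(default_factory=dict)


def classify_rnai(profile: SizeProfile, bias: PositionBias,
                  pp: OverlapSignature,
                  thresholds: RnaiThresholds = RnaiThresholds()) -> RnaiCall:
    """Deterministic rule cascade over the signature battery.

    NOT_DETECTED below the read minimum; EVE_LIKE for single-orientation
    piRNA-window reads with no vsiRNA peak; otherwise a 21-nt both-strand
    peak flags ACTIVE_SIRNA and a U1/A10-supported overlap-10 excess flags
    PIRNA_PINGPONG (combined status when both); else AMBIGUOUS.
    """
    t = thresholds
    total = profile.total
    evidence: dict = {"total_reads": total}
    if total < t.n_min:
        return RnaiCall("NOT_DETECTED", evidence)

    wc = profile.window_counts(t.window)
    window_total = int(wc.sum())
    orient = float(wc.max()) / window_total if window_total else 0.0
    evidence["window_reads"] = window_total
    evidence["single_orientation_fraction"] = orient

    peak21 = profile.length_fraction(21)
    c21 = profile.counts.loc[21]
    minority = float(c21.min()) / c21.sum() if c21.sum() else 0.0
    sirna_peak = peak21 >= t.sirna_peak_fraction and minority >= t.sirna_minority_share
    evidence.update({"fraction_21nt": peak21, "minority_share_21nt": minority,
                     "sirna_peak": sirna_peak})

    z10 = pp.z(10) if (pp.defined and not pp.degenerate) else float("nan")
    u1 = bias.frequency("antisense", "T", 1) if bias.defined("antisense") else float("nan")
    a10 = bias.frequency("sense", "A", 10) if bias.defined("sense") else float("nan")
    pingpong = (not np.isnan(z10) and z10 >= t.z_min
                and not np.isnan(u1) and u1 >= t.min_u1
                and not np.isnan(a10) and a10 >= t.min_a10)
    evidence.update({"z10": z10, "u1_antisense": u1, "a10_sense": a10,
                     "pingpong": pingpong})

    if window_total >= t.n_min and orient >= t.s_eve and not sirna_peak:
        return RnaiCall("EVE_LIKE", evidence)
    if sirna_peak and pingpong:
        return RnaiCall("ACTIVE_SIRNA_PLUS_PIRNA", evidence)
    if sirna_peak:
        return RnaiCall("ACTIVE_SIRNA", evidence)
    if pingpong:
        return RnaiCall("PIRNA_PINGPONG", evidence)
    return RnaiCall("AMBIGUOUS", evidence)


def profile_pair(alignments: Sequence, read_seqs: Mapping[str, str],
                 thresholds: RnaiThresholds = RnaiThresholds()
                 ) -> tuple[SizeProfile, PositionBias, OverlapSignature, RnaiCall]:
    """Convenience: full signature battery and call for one virus-library pair."""
    profile = size_distribution(alignments)
    bias = nucleotide_bias(alignments, read_seqs, window=thresholds.window)
    pp = pingpong_signature(alignments, window=thresholds.window)
    call = classify_rnai(profile, bias, pp, thresholds)
    return profile, bias, pp, call
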