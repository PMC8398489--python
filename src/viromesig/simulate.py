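"""Synthetic genomes, small-RNA libraries and presence panels.

The generator emulates the statistical structure of virus-derived small-RNA
populations in mosquitoes:

* vsiRNA-like reads of 20-22 nt (mode 21) from Dicer-2 cleavage of dsRNA
  replication intermediates, hence present on both genome strands;
* vpiRNA-like reads of 24-29 nt (mode 27) with a uridine bias at position 1
  of antisense (primary) piRNAs, an adenine at position 10 of sense
  (secondary) piRNAs, and the ping-pong geometry: a secondary piRNA's 5'
  end sits exactly 10 nt into its primary partner's 5' end on the opposite
  strand;
* unstructured degradation "noise" reads, uniform in position, strand and
  length (18-32 nt);
* an endogenised-element (EVE) mode in which piRNAs come from one genome
  orientation only and no siRNA class is emitted.

Presence panels emulate multi-library incidence surveys: multi-segment
viruses whose segments co-segregate up to dropout, satellite segments
conditional on their core virus, and cross-library contamination.

Every read carries a ground-truth label keyed by its read identifier, so
labels round-trip through FASTQ/SAM output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .io import make_fastq_record

READ_LEN_MIN = 18
READ_LEN_MAX = 32

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ------------------------------------------------------------------- genomes

@dataclass(frozen=True)
class GenomeSpec:
    """Reference genome recipe: one segment per requested length."""

    segment_lengths: tuple[int, ...]
    gc_fraction: float = 0.5
    seed: int = 0
    id_prefix: str = "seg"

    def __post_init__(self):
        if not self.segment_lengths:
            raise ValueError("segment_lengths must be non-empty")
        if any(int(n) <= 0 for n in self.segment_lengths):
            raise ValueError("segment lengths must be positive")
        if any(int(n) < 100 for n in self.segment_lengths):
            raise ValueError("segment lengths must be >= 100 nt")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


def make_genome(spec: GenomeSpec) -> list[SeqRecord]:
    """Generate i.i.d. A/C/G/T segments at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    records = []
    for i, length in enumerate(spec.segment_lengths, start=1):
        seq = "".join(rng.choice(_BASES, size=int(length), p=probs))
        records.append(SeqRecord(Seq(seq), id=f"{spec.id_prefix}{i}", description=""))
    return records


# ------------------------------------------------------- small-RNA libraries

@dataclass(frozen=True)
class SmallRnaSimConfig:
    """Parameters of one synthetic virus-derived small-RNA library."""

    n_reads: int
    frac_sirna: float = 0.4
    frac_pirna: float = 0.4
    frac_noise: float = 0.2
    sirna_len_probs: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.15, 21: 0.70, 22: 0.15})
    pirna_len_probs: Mapping[int, float] = field(
        default_factory=lambda: {24: 0.05, 25: 0.10, 26: 0.20, 27: 0.35, 28: 0.20, 29: 0.10})
    pingpong_prob: float = 0.5
    u1_bias: float = 0.9
    a10_bias: float = 0.9
    sirna_strand_balance: float = 0.5
    eve_mode: bool = False
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = (self.frac_sirna, self.frac_pirna, self.frac_noise)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("frac_sirna + frac_pirna + frac_noise must sum to 1")
        for name in ("pingpong_prob", "u1_bias", "a10_bias",
                     "sirna_strand_balance", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for probs, lo, hi in ((self.sirna_len_probs, 20, 22),
                              (self.pirna_len_probs, 24, 29)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("length probabilities must sum to 1")
            if any(not lo <= k <= hi for k in probs):
                raise ValueError(f"length support must lie in {lo}..{hi}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")

    def effective(self) -> "SmallRnaSimConfig":
        """EVE mode folds the siRNA mass into the piRNA class."""
        if not self.eve_mode or self.frac_sirna == 0.0:
            return self
        return replace(self, frac_sirna=0.0,
                       frac_pirna=self.frac_pirna + self.frac_sirna)


LABEL_COLUMNS = ["read_id", "source_class", "segment", "strand",
                 "pos5", "start", "end", "length", "partner_id"]


def simulate_small_rna_library(
    segments: Sequence[SeqRecord],
    cfg: SmallRnaSimConfig,
    *,
    allow_empty: bool = False,
    id_prefix: str = "read",
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate one library; returns FASTQ records plus a truth-label table.

    Labels carry class (sirna | primary-pirna | secondary-pirna | noise),
    segment, strand, the genomic 5' position (rightmost interval coordinate
    for antisense reads) and, for ping-pong partners, the partner read id.
    """
    cfg = cfg.effective()
    if cfg.n_reads == 0 and not allow_empty:
        raise ValueError("n_reads = 0; pass allow_empty=True for an empty library")
    seqs = {rec.id: str(rec.seq).upper() for rec in segments}
    if not seqs:
        raise ValueError("at least one reference segment is required")
    for sid, s in seqs.items():
        if len(s) < 50:
            raise ValueError(f"segment {sid} shorter than 50 nt")
        if len(s) < READ_LEN_MAX:
            raise ValueError(f"segment {sid} shorter than the maximum read length")

    rng = np.random.default_rng(cfg.seed)
    seg_ids = list(seqs)
    seg_lens = np.array([len(seqs[s]) for s in seg_ids], dtype=float)
    seg_p = seg_lens / seg_lens.sum()

    n = cfg.n_reads
    classes = rng.choice(
        ["sirna", "pirna", "noise"], size=n,
        p=[cfg.frac_sirna, cfg.frac_pirna, cfg.frac_noise])

    si_lens = np.array(sorted(cfg.sirna_len_probs))
    si_p = np.array([cfg.sirna_len_probs[k] for k in si_lens], dtype=float)
    pi_lens = np.array(sorted(cfg.pirna_len_probs))
    pi_p = np.array([cfg.pirna_len_probs[k] for k in pi_lens], dtype=float)

    records: list[SeqRecord] = []
    labels: list[tuple] = []
    # primaries available as ping-pong partners: (read_id, seg, pos5, first_base)
    primaries: list[tuple[str, str, int, str]] = []

    def emit(read_id, klass, seg, strand, start, length, seq, partner=""):
        pos5 = start if strand == "+" else start + length - 1
        records.append(make_fastq_record(read_id, seq))
        labels.append((read_id, klass, seg, strand, pos5,
                       start, start + length, length, partner))

    def substitute(seq: str) -> str:
        if cfg.error_rate == 0.0:
            return seq
        mask = rng.random(len(seq)) < cfg.error_rate
        if not mask.any():
            return seq
        out = list(seq)
        for i in np.flatnonzero(mask):
            alt = [b for b in "ACGT" if b != out[i]]
            out[i] = alt[rng.integers(3)]
        return "".join(out)

    def read_seq(seg, strand, start, length) -> str:
        frag = seqs[seg][start:start + length]
        return revcomp(frag) if strand == "-" else frag

    counter = 0
    # Pass 1: siRNA, primary (antisense) piRNA and noise reads.  Sense
    # (secondary) piRNAs are deferred so partners exist for pairing.
    deferred_secondary = 0
    for klass in classes:
        if klass == "pirna":
            is_sense = (not cfg.eve_mode) and rng.random() < 0.5
            if is_sense:
                deferred_secondary += 1
                continue
        counter += 1
        read_id = f"{id_prefix}{counter:07d}"
        seg = seg_ids[rng.choice(len(seg_ids), p=seg_p)]
        L_seg = len(seqs[seg])
        if klass == "sirna":
            length = int(rng.choice(si_lens, p=si_p))
            strand = "+" if rng.random() < cfg.sirna_strand_balance else "-"
            start = int(rng.integers(0, L_seg - length + 1))
            seq = read_seq(seg, strand, start, length)
        elif klass == "pirna":  # primary, antisense
            length = int(rng.choice(pi_lens, p=pi_p))
            strand = "-"
            start = int(rng.integers(0, L_seg - length + 1))
            seq = read_seq(seg, strand, start, length)
            if rng.random() < cfg.u1_bias:
                seq = "T" + seq[1:]
            primaries.append((read_id, seg, start + length - 1, seq[0]))
        else:  # noise
            length = int(rng.integers(READ_LEN_MIN, READ_LEN_MAX + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, L_seg - length + 1))
            seq = read_seq(seg, strand, start, length)
        emit(read_id, "primary-pirna" if klass == "pirna" else klass,
             seg, strand, start, length, substitute(seq))

    # Pass 2: sense (secondary) piRNAs, paired with probability pingpong_prob.
    for _ in range(deferred_secondary):
        counter += 1
        read_id = f"{id_prefix}{counter:07d}"
        length = int(rng.choice(pi_lens, p=pi_p))
        partner_id = ""
        placed = False
        if primaries and rng.random() < cfg.pingpong_prob:
            for _attempt in range(10):
                pid, seg, p5, first_base = primaries[rng.integers(len(primaries))]
                start = p5 - 9  # 10-nt 5' overlap: sense 5' at p5 - 9
                if 0 <= start and start + length <= len(seqs[seg]):
                    seq = read_seq(seg, "+", start, length)
                    # position 10 pairs with the partner's position 1
                    seq = seq[:9] + _COMP[first_base] + seq[10:]
                    partner_id = pid
                    placed = True
                    break
        if not placed:
            seg = seg_ids[rng.choice(len(seg_ids), p=seg_p)]
            start = int(rng.integers(0, len(seqs[seg]) - length + 1))
            seq = read_seq(seg, "+", start, length)
            if rng.random() < cfg.a10_bias:
                seq = seq[:9] + "A" + seq[10:]
        emit(read_id, "secondary-pirna", seg, "+", start, length,
             substitute(seq), partner_id)

    label_df = pd.DataFrame(labels, columns=LABEL_COLUMNS)
    return records, label_df


def truth_alignments(labels: pd.DataFrame) -> list:
    """Turn a truth-label table into perfect alignment records."""
    from .mapper import AlignmentRecord

    out = []
    for row in labels.itertuples(index=False):
        length = row.end - row.start
        out.append(AlignmentRecord(
            read_id=row.read_id, segment_id=row.segment, strand=row.strand,
            start=int(row.start), end=int(row.end), mismatches=0,
            identity=1.0, aligned_fraction=1.0))
    return out


# ---------------------------------------------------------- presence panels

@dataclass(frozen=True)
class VirusModel:
    """A virus as an ordered set of reference segments."""

    virus_id: str
    segment_ids: tuple[str, ...]
    satellite_ids: tuple[str, ...] = ()
    prevalence: float = 0.5

    def __post_init__(self):
        if not self.segment_ids:
            raise ValueError("a virus needs at least one segment")
        if not set(self.satellite_ids) <= set(self.segment_ids):
            raise ValueError("satellite_ids must be a subset of segment_ids")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")

    @property
    def core_ids(self) -> tuple[str, ...]:
        return tuple(s for s in self.segment_ids if s not in self.satellite_ids)


@dataclass(frozen=True)
class PanelSimConfig:
    """Multi-library incidence panel recipe."""

    n_libraries: int
    virus_models: tuple[VirusModel, ...]
    segment_dropout: float = 0.0
    satellite_dependence: float = 1.0
    contamination_rate: float = 0.0
    abundance_log10_rpkm_range: tuple[float, float] = (0.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_libraries < 1:
            raise ValueError("n_libraries must be >= 1")
        if not self.virus_models:
            raise ValueError("virus_models must be non-empty")
        for name in ("segment_dropout", "satellite_dependence", "contamination_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.abundance_log10_rpkm_range
        if hi < lo:
            raise ValueError("abundance_log10_rpkm_range must be (lo, hi)")


def simulate_presence_panel(
    cfg: PanelSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate segment-level presence across libraries.

    Returns (presence, rpkm, virus_truth): presence is a boolean
    segments x libraries matrix, rpkm the parallel abundances, and
    virus_truth the virus-level infection table the panel was generated
    from.
    """
    rng = np.random.default_rng(cfg.seed)
    libraries = [f"lib{i + 1:03d}" for i in range(cfg.n_libraries)]
    segment_rows: list[str] = []
    for vm in cfg.virus_models:
        segment_rows.extend(vm.segment_ids)
    if len(set(segment_rows)) != len(segment_rows):
        raise ValueError("segment ids must be unique across viruses")

    presence = pd.DataFrame(False, index=segment_rows, columns=libraries)
    virus_truth = pd.DataFrame(False, index=[vm.virus_id for vm in cfg.virus_models],
                               columns=libraries)
    for lib in libraries:
        for vm in cfg.virus_models:
            infected = rng.random() < vm.prevalence
            virus_truth.loc[vm.virus_id, lib] = infected
            core_any = False
            if infected:
                for seg in vm.core_ids:
                    if rng.random() >= cfg.segment_dropout:
                        presence.loc[seg, lib] = True
                        core_any = True
                for seg in vm.satellite_ids:
                    if rng.random() < cfg.satellite_dependence:
                        presence.loc[seg, lib] = True
            else:
                for seg in vm.segment_ids:
                    if rng.random() < cfg.contamination_rate:
                        presence.loc[seg, lib] = True

    lo, hi = cfg.abundance_log10_rpkm_range
    log_abund = rng.uniform(lo, hi, size=presence.shape)
    rpkm = pd.DataFrame(np.where(presence.to_numpy(), 10.0 ** log_abund, 0.0),
                        index=presence.index, columns=presence.columns)
    return presence, rpkm, virus_truth
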