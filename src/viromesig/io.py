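"""Reading and writing the standard artefacts: FASTA, FASTQ, SAM, TSV.

Sequence formats go through Biopython; SAM goes through pysam.  Internal
coordinates are 0-based half-open on the sense strand; SAM output converts
to its 1-based convention, with flag 16 encoding the antisense strand and
SEQ stored reference-forward as SAM requires.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp


class FormatError(ValueError):
    """Malformed record in a sequence/table file; carries a line number."""

    def __init__(self, message: str, path: str | os.PathLike = "", line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[SeqRecord]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Biopython is lenient for FASTA
        raise FormatError(str(exc), path) from exc
    if not records:
        _raise_if_junk(path, "FASTA")
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    """Parse FASTQ; malformed records raise FormatError with a line number."""
    try:
        return list(SeqIO.parse(str(path), "fastq"))
    except ValueError as exc:
        raise FormatError(str(exc), path, line=_locate_fastq_error(path)) from exc


def _locate_fastq_error(path) -> int | None:
    """Best-effort line number of the first structural FASTQ violation."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            phase = (i - 1) % 4
            if phase == 0 and not line.startswith("@"):
                return i
            if phase == 2 and not line.startswith("+"):
                return i
    return None


def _raise_if_junk(path, fmt: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.strip():
                raise FormatError(f"not a valid {fmt} record", path, line=i)


# ------------------------------------------------------------------------ SAM

def write_sam(alignments: Sequence, segment_lengths: Mapping[str, int],
              read_seqs: Mapping[str, str], path) -> None:
    """Write alignment records (0-based half-open internally) as SAM.

    ``alignments`` needs attributes read_id, segment_id, strand, start, end,
    mismatches.  POS becomes 1-based; NM carries the mismatch count.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": sid, "LN": int(ln)} for sid, ln in segment_lengths.items()],
    }
    tid = {sid: i for i, sid in enumerate(segment_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.reference_id = tid[aln.segment_id]
            seg.reference_start = aln.start
            seg.flag = 16 if aln.strand == "-" else 0
            seq = read_seqs[aln.read_id]
            # SAM stores SEQ in reference-forward orientation.
            seg.query_sequence = revcomp(seq) if aln.strand == "-" else seq
            seg.cigarstring = f"{len(seq)}M"
            seg.mapping_quality = 255
            seg.set_tag("NM", int(aln.mismatches))
            out.write(seg)


def read_sam(path) -> list:
    """Read SAM into AlignmentRecord objects (0-based half-open, read strand)."""
    from .mapper import AlignmentRecord

    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            length = seg.query_length or len(seg.query_sequence or "")
            mism = seg.get_tag("NM") if seg.has_tag("NM") else 0
            records.append(AlignmentRecord(
                read_id=seg.query_name,
                segment_id=seg.reference_name,
                strand="-" if seg.is_reverse else "+",
                start=seg.reference_start,
                end=seg.reference_start + length,
                mismatches=int(mism),
                identity=(length - int(mism)) / length if length else 0.0,
                aligned_fraction=1.0,
            ))
    return records


# ------------------------------------------------------------------------ TSV

def write_presence_tsv(presence: pd.DataFrame, path) -> None:
    """Presence matrix: rows = segments, columns = libraries, cells 0/1."""
    presence.astype(int).to_csv(path, sep="\t", index_label="segment")


def read_presence_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="segment")
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise FormatError("presence matrix cells must be 0/1", path)
    return df.astype(bool)


def alignments_to_frame(alignments: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in alignments],
            "segment_id": [a.segment_id for a in alignments],
            "strand": [a.strand for a in alignments],
            "start": [a.start for a in alignments],
            "end": [a.end for a in alignments],
            "mismatches": [a.mismatches for a in alignments],
            "identity": [a.identity for a in alignments],
            "aligned_fraction": [a.aligned_fraction for a in alignments],
        }
    )


def write_alignments_tsv(alignments: Sequence, path) -> None:
    alignments_to_frame(alignments).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path) -> list:
    from .mapper import AlignmentRecord

    df = pd.read_csv(path, sep="\t")
    return [AlignmentRecord(**row) for row in df.to_dict("records")]


def make_fastq_record(read_id: str, seq: str, qual_char: str = "I") -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [ord(qual_char) - 33] * len(seq)
    return rec
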