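"""Open-reading-frame prediction with a minimum length in amino acids.

ATG-initiated, stop-terminated ORFs under the standard genetic code, both
strands by default, with a 150-aa default minimum (the threshold commonly
used when annotating coding-complete RNA virus genomes).  The nucleotide
interval includes the stop codon; for each (frame, stop) only the longest
ORF (first ATG after the previous break) is reported.  Codons containing
N are untranslatable and break ORFs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from ._util import revcomp

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """One predicted ORF; 0-based half-open interval including the stop codon."""

    segment_id: str
    strand: str
    frame: int
    start: int
    end: int
    length_aa: int
    protein: str
    has_stop: bool = True

    def __post_init__(self):
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF interval must be a whole number of codons")
        expected = (self.end - self.start) // 3 - (1 if self.has_stop else 0)
        if self.length_aa != expected:
            raise ValueError("length_aa inconsistent with interval")


def _scan_strand(seq: str, min_aa: int, include_open: bool
                 ) -> list[tuple[int, int, int, bool]]:
    """All qualifying ORFs on the given (forward-oriented) sequence.

    Returns (start, end, frame, has_stop) in local coordinates.
    """
    L = len(seq)
    out = []
    for frame in range(3):
        start = None
        pos = frame
        while pos + 3 <= L:
            codon = seq[pos:pos + 3]
            if "N" in codon:
                start = None       # untranslatable codon breaks the ORF
            elif codon in _STOPS:
                if start is not None and (pos - start) // 3 >= min_aa:
                    out.append((start, pos + 3, frame, True))
                start = None
            elif codon == "ATG" and start is None:
                start = pos
            pos += 3
        if include_open and start is not None and (pos - start) // 3 >= min_aa:
            out.append((start, pos, frame, False))
    return out


def find_orfs(sequence: str, segment_id: str = "seq", min_aa: int = 150,
              strands: str = "both", include_open: bool = False) -> list[OrfRecord]:
    """Predict ORFs of at least ``min_aa`` codons (excluding the stop)."""
    seq = str(sequence).upper()
    if not seq:
        raise ValueError("empty sequence")
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    L = len(seq)
    records: list[OrfRecord] = []

    def translate(nt: str, has_stop: bool) -> str:
        aa = str(Seq(nt).translate())
        return aa[:-1] if has_stop else aa

    if strands in ("both", "+"):
        for start, end, frame, has_stop in _scan_strand(seq, min_aa, include_open):
            nt = seq[start:end]
            records.append(OrfRecord(
                segment_id=segment_id, strand="+", frame=frame,
                start=start, end=end,
                length_aa=(end - start) // 3 - 1 if has_stop else (end - start) // 3,
                protein=translate(nt, has_stop), has_stop=has_stop))
    if strands in ("both", "-"):
        rc = revcomp(seq)
        for start, end, frame, has_stop in _scan_strand(rc, min_aa, include_open):
            nt = rc[start:end]
            records.append(OrfRecord(
                segment_id=segment_id, strand="-", frame=frame,
                start=L - end, end=L - start,
                length_aa=(end - start) // 3 - 1 if has_stop else (end - start) // 3,
                protein=translate(nt, has_stop), has_stop=has_stop))
    records.sort(key=lambda r: (r.start, r.strand, r.end))
    return records


def write_gff3(orfs: Iterable[OrfRecord], path) -> None:
    """GFF3 output (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, orf in enumerate(orfs, start=1):
            attrs = f"ID=orf{i};length_aa={orf.length_aa};frame={orf.frame}"
            fh.write("\t".join([
                orf.segment_id, "viromesig", "CDS",
                str(orf.start + 1), str(orf.end), ".",
                orf.strand, "0", attrs]) + "\n")


def write_proteins(orfs: Sequence[OrfRecord], path) -> None:
    from Bio.SeqRecord import SeqRecord

    from .io import write_fasta

    records = [
        SeqRecord(Seq(orf.protein),
                  id=f"{orf.segment_id}_orf{i}",
                  description=f"strand={orf.strand} {orf.start}-{orf.end} "
                              f"len={orf.length_aa}aa")
        for i, orf in enumerate(orfs, start=1)
    ]
    write_fasta(records, path)
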