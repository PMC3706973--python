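"""File-format helpers: FASTA, FASTQ, BED and VCF.

FASTA goes through Biopython; FASTQ uses a minimal reader/writer of our own
so that files written by the library round-trip byte-exactly (record ids,
descriptions and quality strings preserved verbatim).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} mapping."""
    with _open(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    """Write (name, sequence) pairs wrapped at ``width`` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with _open(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------- FASTQ

PHRED_OFFSET = 33


@dataclass
class FastqRecord:
    """One FASTQ record; ``desc`` is the free text after the id."""

    id: str
    seq: str
    qual: str  # phred+33 encoded, same length as seq
    desc: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"length mismatch in read {self.id}")

    @property
    def quals(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qual]

    @property
    def header(self) -> str:
        return f"{self.id} {self.desc}" if self.desc else self.id

    def tag(self, key: str) -> str | None:
        """Value of a ``key:value`` token in the description, if present."""
        for token in self.desc.split():
            if token.startswith(key + ":"):
                return token[len(key) + 1 :]
        return None


def read_fastq(path) -> Iterator[FastqRecord]:
    with _open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header: {header!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            if not plus.startswith("+"):
                raise ValueError("malformed FASTQ record (missing '+')")
            qual = handle.readline().rstrip("\n")
            name, _, desc = header[1:].partition(" ")
            yield FastqRecord(name, seq, qual, desc)


def write_fastq(path, records: Iterable[FastqRecord]) -> None:
    with _open(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.header}\n{rec.seq}\n+\n{rec.qual}\n")


def read_fastq_pairs(path1, path2) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    for r1, r2 in zip(read_fastq(path1), read_fastq(path2), strict=True):
        yield r1, r2


def phred_string(quals: Iterable[int]) -> str:
    return "".join(chr(min(q, 93) + PHRED_OFFSET) for q in quals)


# ---------------------------------------------------------------- BED

def write_bed(path, intervals) -> None:
    """Write GenomicInterval-like objects as 0-based BED."""
    with _open(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bed(path):
    from .sequence_model import GenomicInterval

    out = []
    with _open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return out


# ---------------------------------------------------------------- VCF

def write_vcf(path, calls, contigs: Iterable[str] = ()) -> None:
    """Write variant calls as VCF 4.2 (1-based positions).

    ``calls`` holds objects/rows with attributes: contig, pos (0-based),
    ref, alt, genotype ('het'|'hom'), depth, alt_fraction.
    """
    with _open(path, "wt") as handle:
        handle.write("##fileformat=VCFv4.2\n##source=clpptools\n")
        for contig in contigs:
            handle.write(f"##contig=<ID={contig}>\n")
        handle.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n"
        )
        for call in calls:
            gt = "1/1" if call.genotype == "hom" else "0/1"
            handle.write(
                f"{call.contig}\t{call.pos + 1}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t"
                f"DP={call.depth};AF={call.alt_fraction:.4f}\tGT\t{gt}\n"
            )
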