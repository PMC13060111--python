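"""Candidate read extraction.

Reads that can carry a rearranged receptor transcript are selected either
from a genome BAM/SAM (every primary alignment overlapping a V, J or C locus
interval by at least one base) or from raw FASTA/FASTQ, where all reads are
passed through and downstream local alignment resolves strand and locus.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pysam
from Bio import SeqIO

from .germline import LocusIntervals

log = logging.getLogger(__name__)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: Optional[list[int]] = None
    source_strand: str = "unknown"  # plus / minus / unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id!r}: quality length != sequence length")


def extract_candidates_bam(path: str | Path, loci: LocusIntervals) -> list[ReadRecord]:
    """Primary alignments overlapping >=1 base of any V/J/C interval.

    Secondary and supplementary alignments are skipped so each read_id
    appears at most once; minus-strand alignments are emitted as the stored
    (reference-strand) sequence with source_strand='minus'.
    """
    if len(loci) == 0:
        raise ValueError("locus interval set is empty")
    mode = "rb" if str(path).endswith(".bam") else "r"
    out: list[ReadRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            n_mapped += 1
            if aln.query_name in seen:
                continue
            if not loci.overlaps(aln.reference_name, aln.reference_start, aln.reference_end):
                continue
            seq = aln.query_sequence
            if not seq:
                continue
            quals = list(aln.query_qualities) if aln.query_qualities is not None else None
            seen.add(aln.query_name)
            out.append(
                ReadRecord(
                    read_id=aln.query_name,
                    sequence=seq,
                    qualities=quals,
                    source_strand="minus" if aln.is_reverse else "plus",
                )
            )
    if n_mapped == 0:
        warnings.warn(f"{path}: no mapped primary alignments; candidate set is empty")
    return out


def _open_maybe_gz(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def extract_candidates_raw(path: str | Path) -> list[ReadRecord]:
    """Pass-through candidates from FASTA/FASTQ(.gz); order and sequences preserved."""
    with _open_maybe_gz(path) as fh:
        first = fh.read(1)
        if not first:
            return []
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
        fh.seek(0)
        out = []
        for rec in SeqIO.parse(fh, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            out.append(
                ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq),
                    qualities=list(quals) if quals else None,
                    source_strand="unknown",
                )
            )
    return out
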