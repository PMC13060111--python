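"""Germline segment databases and locus interval files.

Immune-receptor annotation needs a reference of unrearranged V, D, J and
constant (C) gene alleles per locus (IGH, IGK, IGL, TRA, TRB).  Alleles are
named IMGT-style, e.g. ``IGHV1-2*02``: locus prefix, segment-class letter,
gene name, and an allele designation after ``*`` (or ``_`` in some published
tables).  This module loads such databases from FASTA, indexes them by
(locus, class), and parses BED files describing the genomic V/J/C intervals
used for candidate-read extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB")
SEGMENT_CLASSES = ("V", "D", "J", "C")

_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_LOCUS_FIELD = re.compile(r"(IGH|IGK|IGL|TRA|TRB)[A-Z0-9]")


class GermlineParseError(ValueError):
    """Raised when a segment name or database record cannot be interpreted."""


def parse_segment_name(name: str) -> tuple[str, str, str, str]:
    """Split an IMGT-style allele name into (locus, segment_class, gene, allele).

    The locus is the first three characters; the fourth character names the
    class when it is V, D or J, otherwise the record is a constant gene
    (``IGHG2`` -> class C).  Both ``*`` and ``_`` are accepted as gene/allele
    separators; the allele is empty when no separator is present.

    >>> parse_segment_name("IGHV3-7*01")
    ('IGH', 'V', 'IGHV3-7', '01')
    >>> parse_segment_name("IGHG2")
    ('IGH', 'C', 'IGHG2', '')
    """
    if not name:
        raise GermlineParseError("empty segment name")
    locus = name[:3].upper()
    if locus not in LOCI:
        raise GermlineParseError(f"unknown locus prefix in segment name {name!r}")
    if "*" in name:
        gene, allele = name.split("*", 1)
    elif "_" in name:
        gene, allele = name.rsplit("_", 1)
        if not allele.isdigit():
            gene, allele = name, ""
    else:
        gene, allele = name, ""
    cls = gene[3].upper() if len(gene) > 3 and gene[3].upper() in ("V", "D", "J") else "C"
    return locus, cls, gene, allele


def canonical_segment_id(gene: str, allele: str) -> str:
    return f"{gene}*{allele}" if allele else gene


@dataclass
class GermlineSegment:
    """One germline allele.

    ``frame_offset`` is the codon phase of the first base (V and J segments
    only; 0 means the first base starts a codon).  ``position_map`` optionally
    maps IMGT amino-acid positions (1-based) to ungapped codon indices
    (0-based); when absent, sequential numbering from ``frame_offset`` is
    assumed (position *i* -> codon *i* - 1).
    """

    segment_id: str
    locus: str
    segment_class: str
    gene: str
    allele: str
    sequence: str
    frame_offset: int = 0
    position_map: Optional[dict[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GermlineParseError(f"segment {self.segment_id!r} has an empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            raise GermlineParseError(
                f"segment {self.segment_id!r} contains characters outside A/C/G/T/N"
            )
        if self.locus not in LOCI:
            raise GermlineParseError(f"segment {self.segment_id!r}: unknown locus {self.locus!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineParseError(
                f"segment {self.segment_id!r}: unknown class {self.segment_class!r}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise GermlineParseError(f"segment {self.segment_id!r}: frame_offset outside 0-2")

    def codon_index(self, imgt_position: int) -> int:
        """Codon index (0-based, from frame_offset) for an IMGT aa position."""
        if self.position_map is not None:
            if imgt_position not in self.position_map:
                raise KeyError(f"no codon mapped at IMGT position {imgt_position}")
            return self.position_map[imgt_position]
        return imgt_position - 1

    def __len__(self) -> int:
        return len(self.sequence)


class GermlineDatabase:
    """Collection of germline segments indexed by (locus, segment_class)."""

    def __init__(self, segments: Iterable[GermlineSegment] = ()) -> None:
        self._by_id: dict[str, GermlineSegment] = {}
        self._index: dict[tuple[str, str], list[GermlineSegment]] = {}
        for seg in segments:
            self.add(seg)

    def add(self, seg: GermlineSegment) -> None:
        key = (seg.gene, seg.allele)
        if any((s.gene, s.allele) == key for s in self._by_id.values()):
            raise GermlineParseError(f"duplicate germline record for {seg.segment_id!r}")
        self._by_id[seg.segment_id] = seg
        self._index.setdefault((seg.locus, seg.segment_class), []).append(seg)

    def get(self, segment_id: str) -> GermlineSegment:
        return self._by_id[segment_id]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def segments(
        self, locus: Optional[str] = None, segment_class: Optional[str] = None
    ) -> list[GermlineSegment]:
        out = []
        for (loc, cls), segs in sorted(self._index.items()):
            if locus is not None and loc != locus:
                continue
            if segment_class is not None and cls != segment_class:
                continue
            out.extend(segs)
        return out

    def loci(self) -> list[str]:
        return sorted({loc for loc, _ in self._index})

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GermlineSegment]:
        return iter(self._by_id.values())

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seg in self._by_id.values():
                fh.write(f">{seg.segment_id}\n{seg.sequence}\n")


def _segment_from_header(header: str, sequence: str, default_locus: Optional[str]) -> GermlineSegment:
    token = header.split()[0]
    name = token
    if "|" in token:
        fields = token.split("|")
        for f in fields:
            if _LOCUS_FIELD.match(f):
                name = f
                break
        else:
            name = fields[0]
    try:
        locus, cls, gene, allele = parse_segment_name(name)
    except GermlineParseError:
        if default_locus is None:
            raise
        locus, cls, gene, allele = default_locus, "V", name, ""
    seq = sequence.upper().replace("U", "T")
    position_map = None
    if "." in seq:
        # IMGT-gapped sequence: dots mark alignment gaps; IMGT position = gapped codon
        seq, position_map = _ungap_imgt(seq)
    return GermlineSegment(
        segment_id=canonical_segment_id(gene, allele),
        locus=locus,
        segment_class=cls,
        gene=gene,
        allele=allele,
        sequence=seq,
        position_map=position_map,
    )


def _ungap_imgt(gapped: str) -> tuple[str, dict[int, int]]:
    """Remove IMGT alignment dots, mapping gapped codon positions to ungapped codons."""
    ungapped = gapped.replace(".", "")
    position_map: dict[int, int] = {}
    consumed = 0
    for pos0 in range(0, len(gapped) - len(gapped) % 3, 3):
        codon = gapped[pos0 : pos0 + 3]
        if "." not in codon and consumed % 3 == 0:
            position_map[pos0 // 3 + 1] = consumed // 3
        consumed += 3 - codon.count(".")
    return ungapped, position_map


def load_germline_fasta(path: str | Path, default_locus: Optional[str] = None) -> GermlineDatabase:
    """Load a germline database from FASTA with IMGT-style headers.

    One segment per record; the locus/class/gene/allele are parsed from the
    header (multi-field ``|``-separated IMGT headers are tolerated).  Records
    whose header cannot be parsed raise unless ``default_locus`` is given.
    Sequences are upper-cased and U is converted to T.
    """
    db = GermlineDatabase()
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    db.add(_segment_from_header(header, "".join(chunks), default_locus))
                header = line[1:]
                if not header.strip():
                    raise GermlineParseError(f"empty FASTA header in {path}")
                chunks = []
            elif line:
                chunks.append(line.strip())
        if header is not None:
            db.add(_segment_from_header(header, "".join(chunks), default_locus))
    return db


@dataclass
class LocusIntervals:
    """Genomic V/J/C intervals per locus, BED convention (0-based half-open)."""

    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    # each entry: (chrom, start, end, locus, segment_class)

    def __post_init__(self) -> None:
        for chrom, start, end, locus, cls in self.intervals:
            if start >= end:
                raise ValueError(f"degenerate interval {chrom}:{start}-{end}")
            if cls not in ("V", "J", "C"):
                raise ValueError(f"interval class must be V, J or C, got {cls!r}")
            if locus not in LOCI:
                raise ValueError(f"unknown locus {locus!r} in interval")

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval on chrom by >=1 base."""
        for c, s, e, _, _ in self.intervals:
            if c == chrom and start < e and s < end:
                return True
        return False

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, locus, cls in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{locus}_{cls}\n")


def load_locus_bed(path: str | Path) -> LocusIntervals:
    """Parse a locus BED file; column 4 carries a ``IGH_V``-style locus/class tag."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >=4 columns")
            chrom, start_s, end_s, tag = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if "_" not in tag:
                raise ValueError(f"{path}:{lineno}: tag {tag!r} is not LOCUS_CLASS")
            locus, cls = tag.rsplit("_", 1)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            intervals.append((chrom, start, end, locus, cls))
    return LocusIntervals(intervals)
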