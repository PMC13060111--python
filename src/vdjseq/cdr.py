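"""CDR1/2/3 extraction by IMGT motifs and positions.

CDR3 starts at the conserved cysteine that ends the V gene — the C of the
last YYC motif in the V-aligned region, or the codon at IMGT position 104
when the motif is absent — and ends at the conserved W/F of the first
[WF]GxG motif in the J-aligned region.  Both anchors are included in the
reported CDR3 (the junction convention).  CDR1 (IMGT positions 27-38) and
CDR2 (56-65) are lifted from the germline V through the alignment; the
conserved C23 and W41 anchors are checked and reported, but a failed anchor
does not suppress the regions.

Reading frames come from the germline ``frame_offset`` propagated through
the alignment path, so a frame can be resolved even when the alignment
starts mid-codon.  Codons interrupted by alignment indels are skipped when
translating anchored regions; out-of-frame junctions (CDR3 length not a
multiple of 3) are reported at the nucleotide level without an amino-acid
string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from .align import LocalHit
from .assign import SegmentAssignment, recover_vdj_sequence
from .germline import GermlineDatabase, GermlineSegment

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = dict(_TABLE.forward_table)
for stop in _TABLE.stop_codons:
    _CODON_AA[stop] = "*"


def translate(nt: str, frame: int = 0) -> str:
    """Standard-code translation; trailing partial codon dropped, stops '*',
    codons with any ambiguous base 'X'."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = nt.upper()[frame:]
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODON_AA.get(seq[i : i + 3], "X"))
    return "".join(out)


@dataclass(frozen=True)
class CdrRuleSet:
    cdr3_v_anchor_motif: str = "YYC"
    cdr3_fallback_position: int = 104
    cdr3_j_terminus_motif: str = "[WF]G.G"
    cdr1_range: tuple[int, int] = (27, 38)
    cdr2_range: tuple[int, int] = (56, 65)
    anchor_c_position: int = 23
    anchor_w_position: int = 41
    anchor_inclusive: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.cdr1_range, self.cdr2_range):
            if not 1 <= lo <= hi <= 130:
                raise ValueError("CDR ranges must be non-empty and within 1-130")
        if self.cdr3_fallback_position <= self.cdr2_range[1]:
            raise ValueError("CDR3 fallback position must lie after CDR2")


@dataclass
class CdrAnnotation:
    cdr1_nt: Optional[str] = None
    cdr1_aa: Optional[str] = None
    cdr2_nt: Optional[str] = None
    cdr2_aa: Optional[str] = None
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    cdr3_read_start: Optional[int] = None
    cdr3_read_end: Optional[int] = None
    anchors_valid: dict[str, bool] = field(default_factory=dict)
    failure_reason: Optional[str] = None


@dataclass
class Rearrangement:
    """A fully annotated read: segment calls + CDRs + recovered VDJ sequence."""

    assignment: SegmentAssignment
    cdr: CdrAnnotation
    vdj_sequence: Optional[str] = None

    @property
    def read_id(self) -> str:
        return self.assignment.read_id


def _germline_to_read_map(hit: LocalHit) -> dict[int, int]:
    """Map aligned germline positions to oriented-read positions via the
    alignment path (positions deleted from the read are absent)."""
    mapping: dict[int, int] = {}
    q, s = hit.q_start, hit.seg_start
    for op, length in hit.ops:
        if op == "M":
            for k in range(length):
                mapping[s + k] = q + k
            q += length
            s += length
        elif op == "I":
            q += length
        else:  # D: germline base absent from read
            s += length
    return mapping


def _read_codons(hit: LocalHit, germ: GermlineSegment) -> dict[int, int]:
    """For each germline codon index fully and contiguously aligned to the
    read, the oriented-read position of its first base."""
    gmap = _germline_to_read_map(hit)
    f = germ.frame_offset
    codons: dict[int, int] = {}
    n_codons = (len(germ.sequence) - f) // 3
    for k in range(n_codons):
        g0 = f + 3 * k
        r0 = gmap.get(g0)
        if r0 is None:
            continue
        if gmap.get(g0 + 1) == r0 + 1 and gmap.get(g0 + 2) == r0 + 2:
            codons[k] = r0
    return codons


def locate_cdr3(
    assignment: SegmentAssignment,
    v_germ: GermlineSegment,
    j_germ: GermlineSegment,
    rules: CdrRuleSet = CdrRuleSet(),
) -> tuple[Optional[int], Optional[int], Optional[str]]:
    """CDR3 interval (0-based half-open) on the oriented read, or a reason code.

    Start: codon of the C in the 3'-most YYC of the V-aligned translation,
    else the codon at IMGT position 104.  End: after the codon of the W/F in
    the 5'-most [WF]GxG of the J-aligned translation.
    """
    if assignment.v is None or assignment.j is None:
        return None, None, "missing_v_or_j"
    if "strand_conflict" in assignment.flags or "j_before_v" in assignment.flags:
        return None, None, "inconsistent_orientation"
    seq = assignment.sequence_oriented
    v_codons = _read_codons(assignment.v.hit, v_germ)
    start: Optional[int] = None
    motif = rules.cdr3_v_anchor_motif
    span = len(motif)
    for k in sorted(v_codons, reverse=True):
        if all(k - i in v_codons for i in range(span)):
            aa = "".join(
                translate(seq[v_codons[k - span + 1 + i] : v_codons[k - span + 1 + i] + 3])
                for i in range(span)
            )
            if aa == motif:
                start = v_codons[k]
                break
    if start is None:
        try:
            fb = v_germ.codon_index(rules.cdr3_fallback_position)
        except KeyError:
            fb = None
        if fb is not None and fb in v_codons:
            start = v_codons[fb]
    if start is None:
        return None, None, "no_v_anchor"
    j_codons = _read_codons(assignment.j.hit, j_germ)
    jpat = re.compile(rules.cdr3_j_terminus_motif)
    end: Optional[int] = None
    ks = sorted(j_codons)
    for k in ks:
        if all(k + i in j_codons for i in range(4)):
            aa = "".join(translate(seq[j_codons[k + i] : j_codons[k + i] + 3]) for i in range(4))
            if jpat.match(aa):
                end = j_codons[k] + 3
                break
    if end is None:
        return None, None, "no_j_anchor"
    if end <= start:
        return None, None, "end_before_start"
    return start, end, None


def extract_cdr1_cdr2(
    assignment: SegmentAssignment,
    v_germ: GermlineSegment,
    rules: CdrRuleSet = CdrRuleSet(),
) -> tuple[Optional[str], Optional[str], dict[str, bool]]:
    """CDR1 and CDR2 nucleotide strings lifted through the V alignment, plus
    the C23/W41 anchor checks.  A region not fully covered by the alignment
    is absent; internal indels are reflected in the lifted substring."""
    if assignment.v is None:
        return None, None, {}
    seq = assignment.sequence_oriented
    v_codons = _read_codons(assignment.v.hit, v_germ)
    gmap = _germline_to_read_map(assignment.v.hit)
    f = v_germ.frame_offset

    def region(lo_pos: int, hi_pos: int) -> Optional[str]:
        try:
            lo_k = v_germ.codon_index(lo_pos)
            hi_k = v_germ.codon_index(hi_pos)
        except KeyError:
            return None
        g_first = f + 3 * lo_k
        g_last = f + 3 * hi_k + 2
        r_first = gmap.get(g_first)
        r_last = gmap.get(g_last)
        if r_first is None or r_last is None or r_last < r_first:
            return None
        return seq[r_first : r_last + 1]

    def anchor_ok(pos: int, expected: str) -> bool:
        try:
            k = v_germ.codon_index(pos)
        except KeyError:
            return False
        r0 = v_codons.get(k)
        return r0 is not None and translate(seq[r0 : r0 + 3]) == expected

    cdr1 = region(*rules.cdr1_range)
    cdr2 = region(*rules.cdr2_range)
    anchors = {
        "c23": anchor_ok(rules.anchor_c_position, "C"),
        "w41": anchor_ok(rules.anchor_w_position, "W"),
    }
    return cdr1, cdr2, anchors


def annotate_rearrangement(
    assignment: SegmentAssignment,
    db: GermlineDatabase,
    rules: CdrRuleSet = CdrRuleSet(),
) -> Rearrangement:
    """Compose segment calls with CDR annotation and VDJ sequence recovery.

    CDR lifting always uses the alignment's own germline hit (consensus
    error correction may relabel a call, but only the aligned germline
    carries coordinates)."""
    ann = CdrAnnotation()
    v_germ = _germ_for(db, assignment.v)
    j_germ = _germ_for(db, assignment.j)
    if v_germ is not None:
        cdr1, cdr2, anchors = extract_cdr1_cdr2(assignment, v_germ, rules)
        ann.cdr1_nt, ann.cdr2_nt = cdr1, cdr2
        ann.anchors_valid = anchors
        if cdr1 is not None and len(cdr1) % 3 == 0:
            ann.cdr1_aa = translate(cdr1)
        if cdr2 is not None and len(cdr2) % 3 == 0:
            ann.cdr2_aa = translate(cdr2)
    vdj = None
    if v_germ is not None and j_germ is not None:
        start, end, reason = locate_cdr3(assignment, v_germ, j_germ, rules)
        ann.failure_reason = reason
        if start is not None:
            ann.cdr3_read_start, ann.cdr3_read_end = start, end
            ann.cdr3_nt = assignment.sequence_oriented[start:end]
            if len(ann.cdr3_nt) % 3 == 0:
                ann.cdr3_aa = translate(ann.cdr3_nt)
        if "strand_conflict" not in assignment.flags and "j_before_v" not in assignment.flags:
            vdj = recover_vdj_sequence(assignment)
    return Rearrangement(assignment=assignment, cdr=ann, vdj_sequence=vdj)


def _germ_for(db: GermlineDatabase, slot) -> Optional[GermlineSegment]:
    if slot is None or slot.hit is None:
        return None
    try:
        return db.get(slot.hit.segment_id)
    except KeyError:
        return None
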