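"""Per-read V/D/J/C segment assignment.

The filtering hierarchy: hits below 90% identity are excluded; V hits
additionally need a raw score of at least 350 (about 175 matched bases at
the default scoring, i.e. substantial V coverage); among survivors the
highest score wins, ties resolved by identity, then aligned length, then
segment id.  D genes are too short and diverse for whole-read ranking, so
they are searched separately inside the V–J interval padded by 20 bp on
each side, keeping only hits strictly above 80% identity.

The read is interpreted on the strand of its V hit (J, then C, as
fallbacks); all downstream coordinates (``SlotCall.start/end``) live on that
oriented sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .align import LocalHit, ScoringScheme, align_to_database, revcomp, smith_waterman
from .candidates import ReadRecord
from .germline import GermlineDatabase

log = logging.getLogger(__name__)

SLOTS = ("V", "D", "J", "C")


@dataclass(frozen=True)
class AssignmentThresholds:
    min_identity_pct: float = 90.0
    min_v_score: int = 350
    d_min_identity_pct: float = 80.0
    vj_pad: int = 20
    # minimal alignment span for a V/J/C call: stands in for the implicit
    # seeding/E-value floor of a seeded aligner, which never reports the
    # ~10 bp chance exact matches a full Smith-Waterman finds everywhere
    min_aligned_length: int = 25

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity_pct <= 100 or not 0 <= self.d_min_identity_pct <= 100:
            raise ValueError("identity thresholds must be in [0, 100]")
        if self.min_v_score < 0 or self.vj_pad < 0:
            raise ValueError("min_v_score and vj_pad must be non-negative")


@dataclass
class SlotCall:
    """A called segment for one slot: the supporting hit (if any), the
    oriented-read interval, and the reported id (which consensus error
    correction may later override)."""

    call_id: str
    hit: Optional[LocalHit] = None
    start: Optional[int] = None
    end: Optional[int] = None
    corrected_from: Optional[str] = None


@dataclass
class SegmentAssignment:
    """Per-read segment calls: the annotation combination G(s) = (Vs, Ds, Js, Cs)."""

    read_id: str
    orientation: str  # '+' or '-': strand of the read the calls are on
    sequence_oriented: str
    locus: Optional[str] = None
    v: Optional[SlotCall] = None
    d: Optional[SlotCall] = None
    j: Optional[SlotCall] = None
    c: Optional[SlotCall] = None
    flags: set[str] = field(default_factory=set)
    position: Optional[int] = None  # anchor for error-correction clustering

    def slot(self, name: str) -> Optional[SlotCall]:
        return getattr(self, name.lower())

    def call(self, name: str) -> Optional[str]:
        sc = self.slot(name)
        return sc.call_id if sc is not None else None

    def combination(self) -> tuple:
        return tuple(self.call(s) for s in SLOTS)


def select_best_call(
    hits: list[LocalHit], segment_class: str, t: AssignmentThresholds = AssignmentThresholds()
) -> Optional[LocalHit]:
    """Apply the class filters and return the top-ranked survivor, if any."""
    survivors = [
        h
        for h in hits
        if h.identity_pct >= t.min_identity_pct and h.aligned_length >= t.min_aligned_length
    ]
    if segment_class == "V":
        survivors = [h for h in survivors if h.raw_score >= t.min_v_score]
    if not survivors:
        return None
    return min(
        survivors, key=lambda h: (-h.raw_score, -h.identity_pct, -h.aligned_length, h.segment_id)
    )


def _oriented_span(hit: LocalHit, orientation: str) -> tuple[int, int]:
    """The hit's read interval in the coordinates of the oriented sequence."""
    if hit.strand == orientation:
        return hit.q_start, hit.q_end
    return hit.read_len - hit.q_end, hit.read_len - hit.q_start


def detect_d_gene(
    assignment: SegmentAssignment,
    d_db: GermlineDatabase,
    scheme: ScoringScheme = ScoringScheme(),
    t: AssignmentThresholds = AssignmentThresholds(),
) -> Optional[LocalHit]:
    """Targeted D search in the padded V–J interval of the oriented read.

    Returns the best D hit strictly above the D identity floor, with
    coordinates lifted back to oriented-read space; None when no D clears
    the bar (the recovered VDJ sequence still spans the region either way).
    """
    if assignment.v is None or assignment.j is None:
        return None
    seq = assignment.sequence_oriented
    v_end = assignment.v.end
    j_start = assignment.j.start
    lo = max(0, v_end - t.vj_pad)
    hi = min(len(seq), j_start + t.vj_pad)
    if hi <= lo:
        return None
    window = seq[lo:hi]
    best: Optional[LocalHit] = None
    for seg in d_db.segments(locus=assignment.locus, segment_class="D"):
        hit = smith_waterman(window, seg.sequence, scheme, assignment.read_id, seg.segment_id, "+")
        if hit is None or hit.identity_pct <= t.d_min_identity_pct:
            continue
        if best is None or (
            (-hit.raw_score, -hit.identity_pct, -hit.aligned_length, hit.segment_id)
            < (-best.raw_score, -best.identity_pct, -best.aligned_length, best.segment_id)
        ):
            best = hit
    if best is None:
        return None
    best.q_start += lo
    best.q_end += lo
    best.read_len = len(seq)
    return best


def assign_read(
    read: ReadRecord,
    db: GermlineDatabase,
    scheme: ScoringScheme = ScoringScheme(),
    t: AssignmentThresholds = AssignmentThresholds(),
    locus: Optional[str] = None,
) -> Optional[SegmentAssignment]:
    """Full per-read assignment: V, J, C independently; then the targeted D search.

    Returns None when no class yields a call.  When the V and J calls sit on
    opposite strands the assignment is flagged ('strand_conflict') and the D
    search is skipped; when J precedes V on the chosen strand the read is
    flagged ('j_before_v') and excluded from CDR3 extraction downstream.
    """
    calls: dict[str, Optional[LocalHit]] = {}
    for cls in ("V", "J", "C"):
        hits = align_to_database(read, db, cls, scheme, locus=locus)
        calls[cls] = select_best_call(hits, cls, t)
    if all(h is None for h in calls.values()):
        return None
    anchor = calls["V"] or calls["J"] or calls["C"]
    orientation = anchor.strand
    oriented = read.sequence if orientation == "+" else revcomp(read.sequence)
    locus_called = None
    for cls in ("V", "J", "C"):
        if calls[cls] is not None:
            locus_called = _locus_of(db, calls[cls].segment_id)
            break
    asn = SegmentAssignment(
        read_id=read.read_id,
        orientation=orientation,
        sequence_oriented=oriented,
        locus=locus_called,
    )
    for cls, attr in (("V", "v"), ("J", "j"), ("C", "c")):
        hit = calls[cls]
        if hit is None:
            continue
        start, end = _oriented_span(hit, orientation)
        setattr(asn, attr, SlotCall(call_id=hit.segment_id, hit=hit, start=start, end=end))
    if asn.v is not None and asn.j is not None:
        if asn.v.hit.strand != asn.j.hit.strand:
            asn.flags.add("strand_conflict")
            log.warning("read %s: V and J hits on opposite strands", read.read_id)
        elif asn.j.start < asn.v.start:
            asn.flags.add("j_before_v")
        else:
            d_hit = detect_d_gene(asn, db, scheme, t)
            if d_hit is not None:
                asn.d = SlotCall(
                    call_id=d_hit.segment_id, hit=d_hit, start=d_hit.q_start, end=d_hit.q_end
                )
    if asn.v is not None:
        asn.position = asn.v.hit.seg_start
    return asn


def _locus_of(db: GermlineDatabase, segment_id: str) -> Optional[str]:
    try:
        return db.get(segment_id).locus
    except KeyError:
        return None


def recover_vdj_sequence(assignment: SegmentAssignment) -> str:
    """The contiguous oriented-read substring from V start through J end.

    This recovers the complete VDJ region even when no D passed the identity
    filter: short or heavily mutated D remnants are still physically present
    between the located V and J.
    """
    if assignment.v is None or assignment.j is None:
        raise ValueError("recover_vdj_sequence needs both V and J calls")
    return assignment.sequence_oriented[assignment.v.start : assignment.j.end]
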