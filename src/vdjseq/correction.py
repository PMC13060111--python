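"""Consensus-based correction of annotation combinations.

Long-read platforms (Nanopore especially) leave residual base errors that
can flip a single segment call on an otherwise well-supported read.  Reads
are grouped into 50-bp windows of alignment start position; within each
window the modal annotation combination (Vd, Dd, Jd, Cd) is taken as the
consensus, and any member deviating from it in exactly one of the four
slots is corrected to the dominant call.  Members deviating in two or more
slots are genuinely different rearrangements and are left untouched.

A window corrects only when the dominant combination has at least
``min_dominant_support`` members (default 2) and strictly more support than
the deviant's own combination: a 1-vs-1 window has no consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

SLOTS = ("V", "D", "J", "C")

Combination = tuple  # (v, d, j, c), each Optional[str]; absent slots are None


@dataclass
class WindowMember:
    read_id: str
    start_position: int
    combination: Combination
    score: float = 0.0  # summed hit scores, used only for dominant tie-breaks


@dataclass
class Correction:
    read_id: str
    slot: str
    old: Optional[str]
    new: Optional[str]
    window_anchor: int


@dataclass
class CorrectionWindow:
    anchor_start: int
    members: list[WindowMember]
    dominant: Optional[Combination] = None
    corrections: list[Correction] = field(default_factory=list)


def deviation_count(s: Combination, d: Combination) -> int:
    """N(s): number of V/D/J/C slots where s differs from the dominant d
    (missing slots compare as a distinct 'absent' value)."""
    return sum(1 for a, b in zip(s, d) if a != b)


def cluster_by_start(
    members: Sequence[WindowMember], window_bp: int = 50
) -> list[CorrectionWindow]:
    """Greedy fixed-anchor clustering: sort by start; a new window opens when
    a start exceeds anchor_start + window_bp - 1.  Every member lands in
    exactly one window."""
    ordered = sorted(members, key=lambda m: (m.start_position, m.read_id))
    windows: list[CorrectionWindow] = []
    for m in ordered:
        if windows and m.start_position < windows[-1].anchor_start + window_bp:
            windows[-1].members.append(m)
        else:
            windows.append(CorrectionWindow(anchor_start=m.start_position, members=[m]))
    return windows


def correct_window(w: CorrectionWindow, min_dominant_support: int = 2) -> CorrectionWindow:
    """Apply the consensus rule in place and return the window.

    Dominant = most frequent combination (ties by highest summed hit score,
    then lexicographic).  Members whose deviation count is exactly 1 have
    the deviating slot replaced by the dominant slot; all corrections are
    logged.  Idempotent: corrected members join the dominant combination.
    """
    counts = Counter(m.combination for m in w.members)
    scores: dict[Combination, float] = {}
    for m in w.members:
        scores[m.combination] = scores.get(m.combination, 0.0) + m.score
    w.dominant = min(
        counts,
        key=lambda c: (-counts[c], -scores.get(c, 0.0), tuple(x if x is not None else "" for x in c)),
    )
    w.corrections = []
    if counts[w.dominant] < min_dominant_support:
        return w
    for m in w.members:
        if m.combination == w.dominant:
            continue
        if counts[m.combination] >= counts[w.dominant]:
            continue  # no consensus over an equally supported combination
        if deviation_count(m.combination, w.dominant) != 1:
            continue
        new_combo = list(m.combination)
        for idx, slot in enumerate(SLOTS):
            if m.combination[idx] != w.dominant[idx]:
                w.corrections.append(
                    Correction(
                        read_id=m.read_id,
                        slot=slot,
                        old=m.combination[idx],
                        new=w.dominant[idx],
                        window_anchor=w.anchor_start,
                    )
                )
                new_combo[idx] = w.dominant[idx]
        m.combination = tuple(new_combo)
    return w


def correct_assignments(
    assignments: list,
    window_bp: int = 50,
    min_dominant_support: int = 2,
    scope: str = "window",
) -> list[Correction]:
    """Run consensus correction over SegmentAssignments and write the
    corrected call ids back into their slots.

    The clustering anchor is the assignment's ``position`` (genomic
    alignment start when extraction came from a BAM; otherwise the V hit's
    germline start, so correction stays usable in alignment-free mode).
    Assignments without a position pass through uncorrected.  ``scope`` is
    'window' (default) or 'dataset' (one window spanning everything).
    """
    from .assign import SlotCall  # local import to avoid a cycle

    eligible = [a for a in assignments if a.position is not None]
    members = [
        WindowMember(
            read_id=a.read_id,
            start_position=a.position,
            combination=a.combination(),
            score=sum(
                s.hit.raw_score for s in (a.v, a.d, a.j, a.c) if s is not None and s.hit is not None
            ),
        )
        for a in eligible
    ]
    if scope == "dataset":
        windows = [CorrectionWindow(anchor_start=0, members=list(members))] if members else []
    else:
        windows = cluster_by_start(members, window_bp)
    log: list[Correction] = []
    by_id = {a.read_id: a for a in eligible}
    for w in windows:
        correct_window(w, min_dominant_support)
        for corr in w.corrections:
            a = by_id[corr.read_id]
            attr = corr.slot.lower()
            sc = getattr(a, attr)
            if corr.new is None:
                setattr(a, attr, None)
            elif sc is None:
                setattr(a, attr, SlotCall(call_id=corr.new, corrected_from=None))
            else:
                sc.corrected_from = sc.call_id
                sc.call_id = corr.new
            log.append(corr)
    return log


def write_correction_log(log: list[Correction], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tslot\told_call\tnew_call\twindow_anchor\n")
        for c in log:
            fh.write(
                f"{c.read_id}\t{c.slot}\t{c.old or ''}\t{c.new or ''}\t{c.window_anchor}\n"
            )
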