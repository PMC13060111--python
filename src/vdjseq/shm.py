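"""Somatic hypermutation flagging and putative novel segment discovery.

Rearranged immunoglobulin genes accumulate point mutations during affinity
maturation, lowering identity to the germline.  A read region whose best
germline hit falls below 85% identity is flagged as SHM-bearing; unique
such regions seen in at least two reads are reported as putative novel
subclasses (heavy SHM and genuinely novel alleles are not adjudicated —
the report labels both "putative novel").  Singleton sequences are dropped
to suppress sequencing-error artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .align import LocalHit

DEFAULT_SHM_IDENTITY_PCT = 85.0


@dataclass
class NovelCandidate:
    representative_sequence: str
    best_segment_id: str
    best_identity_pct: float
    segment_class: str
    locus: str
    support: int


def classify_shm(best_hit: LocalHit, shm_identity_pct: float = DEFAULT_SHM_IDENTITY_PCT) -> bool:
    """True iff the read's top germline hit has identity strictly below the bar."""
    return best_hit.identity_pct < shm_identity_pct


def find_novel_candidates(
    rearrangements: Iterable,
    min_support: int = 2,
    shm_identity_pct: float = DEFAULT_SHM_IDENTITY_PCT,
) -> list[NovelCandidate]:
    """Deduplicate aligned segment sub-sequences across reads and report the
    groups below the identity bar with enough read support.

    Uniqueness is exact string identity on the oriented aligned region; no
    clustering of near-identical variants is attempted.
    """
    groups: dict[tuple[str, str], dict] = {}
    for r in rearrangements:
        a = r.assignment
        for cls in ("V", "D", "J", "C"):
            sc = a.slot(cls)
            if sc is None or sc.hit is None or sc.start is None:
                continue
            subseq = a.sequence_oriented[sc.start : sc.end]
            if not subseq:
                continue
            key = (cls, subseq)
            g = groups.setdefault(
                key,
                {"reads": set(), "best_identity": -1.0, "best_segment": None, "locus": a.locus},
            )
            g["reads"].add(a.read_id)
            if sc.hit.identity_pct > g["best_identity"]:
                g["best_identity"] = sc.hit.identity_pct
                g["best_segment"] = sc.hit.segment_id
    out = []
    for (cls, subseq), g in groups.items():
        if len(g["reads"]) < min_support:
            continue
        if g["best_identity"] >= shm_identity_pct:
            continue
        out.append(
            NovelCandidate(
                representative_sequence=subseq,
                best_segment_id=g["best_segment"],
                best_identity_pct=g["best_identity"],
                segment_class=cls,
                locus=g["locus"] or "",
                support=len(g["reads"]),
            )
        )
    out.sort(key=lambda c: (-c.support, c.segment_class, c.representative_sequence))
    return out


def shm_density(rearrangements: Iterable, shm_identity_pct: float = DEFAULT_SHM_IDENTITY_PCT) -> dict:
    """Per-locus SHM summary: flagged segment regions and counts per aligned base."""
    stats: dict[str, dict[str, float]] = {}
    for r in rearrangements:
        a = r.assignment
        if a.locus is None:
            continue
        st = stats.setdefault(a.locus, {"flagged": 0, "regions": 0, "aligned_bases": 0})
        for cls in ("V", "D", "J", "C"):
            sc = a.slot(cls)
            if sc is None or sc.hit is None:
                continue
            st["regions"] += 1
            st["aligned_bases"] += sc.hit.aligned_length
            if classify_shm(sc.hit, shm_identity_pct):
                st["flagged"] += 1
    for st in stats.values():
        st["flagged_per_base"] = st["flagged"] / st["aligned_bases"] if st["aligned_bases"] else 0.0
    return stats


def write_novel_report(candidates: list[NovelCandidate], tsv_path, fasta_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("sequence\tbest_segment_id\tbest_identity_pct\tsegment_class\tlocus\tsupport\n")
        for c in candidates:
            fh.write(
                f"{c.representative_sequence}\t{c.best_segment_id}\t{c.best_identity_pct:.2f}\t"
                f"{c.segment_class}\t{c.locus}\t{c.support}\n"
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for i, c in enumerate(candidates, 1):
                fh.write(
                    f">novel_{i} class={c.segment_class} locus={c.locus} "
                    f"best={c.best_segment_id} identity={c.best_identity_pct:.2f} support={c.support}\n"
                    f"{c.representative_sequence}\n"
                )
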