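"""Clonotype and usage summaries; AIRR Rearrangement TSV output.

A clonotype groups reads sharing gene-level V/(D)/J calls and the CDR3
amino-acid sequence.  Usage tables count segment calls per slot at gene or
allele granularity.  The primary per-read output is a tab-separated table
using AIRR Rearrangement column names (sequence_id, v_call, junction
coordinates 1-based inclusive, ...), one row per read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd


def gene_of(segment_id: Optional[str]) -> Optional[str]:
    """Strip the allele designation: IGHV1-2*02 -> IGHV1-2 (also IGHJ5_02)."""
    if segment_id is None:
        return None
    if "*" in segment_id:
        return segment_id.split("*", 1)[0]
    if "_" in segment_id:
        gene, allele = segment_id.rsplit("_", 1)
        if allele.isdigit():
            return gene
    return segment_id


@dataclass
class ClonotypeRecord:
    key: tuple  # (v_gene, d_gene, j_gene, cdr3_aa)
    count: int
    frequency: float


def build_clonotypes(
    rearrangements: Iterable, min_frequency: float = 0.0, level: str = "gene"
) -> list[ClonotypeRecord]:
    """Group by (V, D, J, CDR3aa) key; frequency over all complete-key reads.

    Reads lacking a V call, J call or CDR3 amino-acid sequence are excluded;
    a missing D is its own key value.  Records below ``min_frequency`` are
    dropped after frequencies are computed (surviving frequencies are not
    renormalized).
    """
    reduce = gene_of if level == "gene" else (lambda x: x)
    counts: dict[tuple, int] = {}
    for r in rearrangements:
        a = r.assignment
        if a.call("V") is None or a.call("J") is None or r.cdr.cdr3_aa is None:
            continue
        key = (reduce(a.call("V")), reduce(a.call("D")), reduce(a.call("J")), r.cdr.cdr3_aa)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    records = [
        ClonotypeRecord(key=k, count=n, frequency=n / total) for k, n in counts.items()
    ]
    if min_frequency > 0:
        records = [r for r in records if r.frequency >= min_frequency]
    records.sort(key=lambda r: (-r.count, tuple(x if x is not None else "" for x in r.key)))
    return records


def usage_table(
    rearrangements: Iterable, slot: str, level: str = "gene"
) -> dict[str, tuple[int, float]]:
    """Mapping segment name -> (count, proportion) over reads with that slot
    called; uncalled reads are excluded from the denominator."""
    reduce = gene_of if level == "gene" else (lambda x: x)
    counts: dict[str, int] = {}
    for r in rearrangements:
        call = r.assignment.call(slot)
        if call is None:
            continue
        name = reduce(call)
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    return {name: (n, n / total) for name, n in sorted(counts.items())}


AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "locus",
    "rev_comp",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "cdr1",
    "cdr1_aa",
    "cdr2",
    "cdr2_aa",
    "cdr3",
    "cdr3_aa",
    "junction_start",
    "junction_end",
    "v_score",
    "v_identity",
    "d_score",
    "d_identity",
    "j_score",
    "j_identity",
    "c_score",
    "c_identity",
    "vdj_sequence",
]


def rearrangements_to_frame(rearrangements: Iterable) -> pd.DataFrame:
    rows = []
    for r in rearrangements:
        a = r.assignment
        row: dict = {
            "sequence_id": a.read_id,
            "sequence": a.sequence_oriented,
            "locus": a.locus,
            "rev_comp": "T" if a.orientation == "-" else "F",
            "cdr1": r.cdr.cdr1_nt,
            "cdr1_aa": r.cdr.cdr1_aa,
            "cdr2": r.cdr.cdr2_nt,
            "cdr2_aa": r.cdr.cdr2_aa,
            "cdr3": r.cdr.cdr3_nt,
            "cdr3_aa": r.cdr.cdr3_aa,
            # AIRR convention: 1-based inclusive coordinates in the output
            "junction_start": None
            if r.cdr.cdr3_read_start is None
            else r.cdr.cdr3_read_start + 1,
            "junction_end": r.cdr.cdr3_read_end,
            "vdj_sequence": r.vdj_sequence,
        }
        for cls in ("v", "d", "j", "c"):
            sc = getattr(a, cls)
            row[f"{cls}_call"] = sc.call_id if sc is not None else None
            row[f"{cls}_score"] = sc.hit.raw_score if sc is not None and sc.hit else None
            row[f"{cls}_identity"] = (
                round(sc.hit.identity_pct, 4) if sc is not None and sc.hit else None
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(rearrangements: Iterable, path) -> pd.DataFrame:
    """AIRR Rearrangement TSV, one row per read, header exactly once."""
    df = rearrangements_to_frame(rearrangements)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_airr(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)


def write_clonotypes(records: list[ClonotypeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("v_gene\td_gene\tj_gene\tcdr3_aa\tcount\tfrequency\n")
        for r in records:
            v, d, j, cdr3 = (x if x is not None else "" for x in r.key)
            fh.write(f"{v}\t{d}\t{j}\t{cdr3}\t{r.count}\t{r.frequency:.6g}\n")


def write_usage(table: dict[str, tuple[int, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcount\tproportion\n")
        for name, (n, p) in table.items():
            fh.write(f"{name}\t{n}\t{p:.6g}\n")
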