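"""Scoring called segments and recombinations against simulation truth.

Metrics follow the benchmark convention: gene-set mode compares the set of
called gene labels with the set of true labels (recall = |intersection| /
|truth|, precision = |intersection| / |called|); per-read mode scores each
read's call against its transcript's truth.  F1 is the harmonic mean
2rp/(r+p).  Concordance between two call sets is the fraction of the
reference set recovered, optionally after a clonotype-frequency floor on
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .simulate import SimTruth
from .summary import gene_of


@dataclass(frozen=True)
class EvalMetrics:
    recall: float
    precision: float
    degenerate: bool = False  # no calls / no truth: precision reported as 0 with a flag

    @property
    def f1(self) -> float:
        return f1_score(self.recall, self.precision)


def f1_score(recall: float, precision: float) -> float:
    """F1 = 2 * recall * precision / (recall + precision); 0 when both are 0."""
    if not 0 <= recall <= 1 or not 0 <= precision <= 1:
        raise ValueError("recall and precision must be in [0, 1]")
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


_SLOT_COLS = {"V": "v_call", "D": "d_call", "J": "j_call", "C": "c_call"}


def _norm(call: Optional[str], level: str) -> Optional[str]:
    if call is None or (isinstance(call, float) and pd.isna(call)) or call == "":
        return None
    return gene_of(call) if level == "gene" else call


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    from .summary import rearrangements_to_frame

    return rearrangements_to_frame(calls)


def score_segments(
    calls,
    truth: SimTruth,
    mode: str = "gene_set",
    level: str = "gene",
) -> dict[str, EvalMetrics]:
    """Per segment class, compare calls with truth.

    ``calls`` is an AIRR-style DataFrame (or a list of rearrangements);
    reads absent from the call table count as false negatives in per_read
    mode.  Truth classes with no true segments (e.g. D on a light chain)
    are omitted from the result.
    """
    df = _calls_frame(calls)
    by_read = df.set_index("sequence_id") if len(df) else df
    out: dict[str, EvalMetrics] = {}
    for cls, col in _SLOT_COLS.items():
        true_by_read = {}
        for rt in truth.reads.values():
            t = truth.transcripts[rt.transcript_id]
            true_by_read[rt.read_id] = _norm(getattr(t, cls.lower()), level)
        truth_labels = {v for v in true_by_read.values() if v is not None}
        if not truth_labels:
            continue
        called_by_read = {}
        if len(df):
            for rid, row in by_read.iterrows():
                called_by_read[rid] = _norm(row.get(col), level)
        called_labels = {v for v in called_by_read.values() if v is not None}
        if mode == "gene_set":
            inter = truth_labels & called_labels
            recall = len(inter) / len(truth_labels)
            if not called_labels:
                out[cls] = EvalMetrics(recall=recall, precision=0.0, degenerate=True)
            else:
                out[cls] = EvalMetrics(recall=recall, precision=len(inter) / len(called_labels))
        elif mode == "per_read":
            truth_reads = [r for r, v in true_by_read.items() if v is not None]
            correct = sum(1 for r in truth_reads if called_by_read.get(r) == true_by_read[r])
            recall = correct / len(truth_reads) if truth_reads else 0.0
            called_reads = [r for r, v in called_by_read.items() if v is not None]
            good = sum(1 for r in called_reads if true_by_read.get(r) == called_by_read[r])
            if not called_reads:
                out[cls] = EvalMetrics(recall=recall, precision=0.0, degenerate=True)
            else:
                out[cls] = EvalMetrics(recall=recall, precision=good / len(called_reads))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def score_recombinations(
    calls,
    truth: SimTruth,
    with_d: bool = True,
    mode: str = "gene_set",
    level: str = "gene",
) -> EvalMetrics:
    """Compare called (V, D, J) — or (V, J) — gene tuples against truth.

    gene_set mode (default) scores unique tuples; per_read scores reads."""
    df = _calls_frame(calls)

    def truth_tuple(t):
        if with_d:
            return (_norm(t.v, level), _norm(t.d, level), _norm(t.j, level))
        return (_norm(t.v, level), _norm(t.j, level))

    def call_tuple(row):
        v = _norm(row.get("v_call"), level)
        j = _norm(row.get("j_call"), level)
        if v is None or j is None:
            return None
        if with_d:
            return (v, _norm(row.get("d_call"), level), j)
        return (v, j)

    true_by_read = {
        rt.read_id: truth_tuple(truth.transcripts[rt.transcript_id])
        for rt in truth.reads.values()
    }
    called_by_read = {}
    for _, row in df.iterrows():
        tup = call_tuple(row)
        if tup is not None:
            called_by_read[row["sequence_id"]] = tup
    if mode == "gene_set":
        truth_set = set(true_by_read.values())
        called_set = set(called_by_read.values())
        inter = truth_set & called_set
        recall = len(inter) / len(truth_set) if truth_set else 0.0
        if not called_set:
            return EvalMetrics(recall=recall, precision=0.0, degenerate=True)
        return EvalMetrics(recall=recall, precision=len(inter) / len(called_set))
    if mode == "per_read":
        truth_reads = list(true_by_read)
        correct = sum(1 for r in truth_reads if called_by_read.get(r) == true_by_read[r])
        recall = correct / len(truth_reads) if truth_reads else 0.0
        called_reads = list(called_by_read)
        good = sum(1 for r in called_reads if true_by_read.get(r) == called_by_read[r])
        if not called_reads:
            return EvalMetrics(recall=recall, precision=0.0, degenerate=True)
        return EvalMetrics(recall=recall, precision=good / len(called_reads))
    raise ValueError(f"unknown mode {mode!r}")


def concordance(
    set_a: Iterable,
    set_b,
    frequency_floor: float = 0.0,
) -> float:
    """Fraction of reference-set (B) elements recovered by A: |A & B| / |B|.

    ``set_b`` may be a mapping element -> frequency, in which case elements
    below ``frequency_floor`` are dropped first.  1.0 when B is empty (by
    convention: nothing to recover)."""
    a = set(set_a)
    if isinstance(set_b, Mapping):
        b = {k for k, freq in set_b.items() if freq >= frequency_floor}
    else:
        if frequency_floor > 0:
            raise ValueError("frequency_floor needs a mapping with frequencies")
        b = set(set_b)
    if not b:
        return 1.0
    return len(a & b) / len(b)


def metrics_frame(
    segment_metrics: dict[str, EvalMetrics],
    recombination: Optional[EvalMetrics] = None,
    locus: str = "",
) -> pd.DataFrame:
    rows = []
    for cls, m in segment_metrics.items():
        rows.append(
            {
                "locus": locus,
                "target": cls,
                "recall": round(m.recall, 6),
                "precision": round(m.precision, 6),
                "f1": round(m.f1, 6),
            }
        )
    if recombination is not None:
        rows.append(
            {
                "locus": locus,
                "target": "recombination",
                "recall": round(recombination.recall, 6),
                "precision": round(recombination.precision, 6),
                "f1": round(recombination.f1, 6),
            }
        )
    return pd.DataFrame(rows, columns=["locus", "target", "recall", "precision", "f1"])
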