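"""End-to-end annotation pipeline and its configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .align import ScoringScheme
from .assign import AssignmentThresholds, SegmentAssignment, assign_read
from .candidates import ReadRecord
from .cdr import CdrRuleSet, Rearrangement, annotate_rearrangement
from .correction import Correction, correct_assignments, write_correction_log
from .germline import GermlineDatabase
from .shm import NovelCandidate, find_novel_candidates, shm_density, write_novel_report
from .summary import build_clonotypes, usage_table, write_airr, write_clonotypes, write_usage

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds in one place; defaults are the pipeline's
    published operating point (identity 90%, V score 350, D identity 80%,
    20 bp pad, 50 bp correction window, SHM bar 85%, novel support 2)."""

    min_identity_pct: float = 90.0
    min_v_score: int = 350
    d_min_identity_pct: float = 80.0
    vj_pad: int = 20
    window_bp: int = 50
    correction_scope: str = "window"  # or "dataset"
    correction: bool = True
    min_dominant_support: int = 2
    shm_identity_pct: float = 85.0
    min_support: int = 2
    min_frequency: float = 0.0
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    reference_preset: Optional[str] = None
    seed: int = 0

    def thresholds(self) -> AssignmentThresholds:
        return AssignmentThresholds(
            min_identity_pct=self.min_identity_pct,
            min_v_score=self.min_v_score,
            d_min_identity_pct=self.d_min_identity_pct,
            vj_pad=self.vj_pad,
        )

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    rearrangements: list[Rearrangement] = field(default_factory=list)
    corrections: list[Correction] = field(default_factory=list)
    novel: list[NovelCandidate] = field(default_factory=list)
    n_candidates: int = 0
    n_assigned: int = 0

    def summary(self) -> dict:
        return {
            "candidates": self.n_candidates,
            "assigned": self.n_assigned,
            "rearrangements": len(self.rearrangements),
            "with_cdr3": sum(1 for r in self.rearrangements if r.cdr.cdr3_nt is not None),
            "corrections": len(self.corrections),
            "novel_candidates": len(self.novel),
        }


def annotate_reads(
    reads: list[ReadRecord],
    db: GermlineDatabase,
    config: PipelineConfig = PipelineConfig(),
    rules: CdrRuleSet = CdrRuleSet(),
) -> PipelineResult:
    """Assign segments, correct annotation combinations, annotate CDRs,
    and collect putative novel events for a candidate read set."""
    scheme = config.scheme()
    t = config.thresholds()
    assignments: list[SegmentAssignment] = []
    for read in reads:
        asn = assign_read(read, db, scheme, t)
        if asn is not None:
            assignments.append(asn)
    corrections: list[Correction] = []
    if config.correction:
        corrections = correct_assignments(
            assignments,
            window_bp=config.window_bp,
            min_dominant_support=config.min_dominant_support,
            scope=config.correction_scope,
        )
    rearrangements = [annotate_rearrangement(a, db, rules) for a in assignments]
    novel = find_novel_candidates(
        rearrangements, min_support=config.min_support, shm_identity_pct=config.shm_identity_pct
    )
    return PipelineResult(
        rearrangements=rearrangements,
        corrections=corrections,
        novel=novel,
        n_candidates=len(reads),
        n_assigned=len(assignments),
    )


def write_outputs(result: PipelineResult, out_prefix: str | Path, config: PipelineConfig) -> dict:
    """Write the AIRR table, clonotype and usage tables, correction log,
    novel-candidate report and a machine-readable run summary."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "airr": f"{prefix}.airr.tsv",
        "clonotypes": f"{prefix}.clonotypes.tsv",
        "usage_v": f"{prefix}.usage_v.tsv",
        "usage_j": f"{prefix}.usage_j.tsv",
        "usage_c": f"{prefix}.usage_c.tsv",
        "novel": f"{prefix}.novel.tsv",
        "summary": f"{prefix}.summary.json",
    }
    write_airr(result.rearrangements, paths["airr"])
    write_clonotypes(
        build_clonotypes(result.rearrangements, min_frequency=config.min_frequency),
        paths["clonotypes"],
    )
    for slot in ("V", "J", "C"):
        write_usage(usage_table(result.rearrangements, slot), paths[f"usage_{slot.lower()}"])
    write_novel_report(result.novel, paths["novel"])
    if config.correction:
        paths["corrections"] = f"{prefix}.corrections.tsv"
        write_correction_log(result.corrections, paths["corrections"])
    summary = result.summary()
    summary["shm"] = shm_density(result.rearrangements, config.shm_identity_pct)
    summary["config"] = asdict(config)
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return paths
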