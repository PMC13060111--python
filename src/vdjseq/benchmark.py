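"""Closed-loop simulation benchmarks.

Reproduces the simulation study design at desk scale: a synthetic
pairwise-divergent germline set per locus, randomized recombination with
every segment expressed, platform-shaped reads at 20x coverage with
germline mutations at 1e-4, annotation with default thresholds, and
gene-set scoring against ground truth.
"""

from __future__ import annotations

from typing import Optional

from .candidates import ReadRecord
from .evaluate import score_recombinations, score_segments
from .pipeline import PipelineConfig, annotate_reads
from .simulate import SimConfig, make_synthetic_germline_db, simulate_reads, simulate_repertoire
from .summary import rearrangements_to_frame

# study design per locus: (n_v, n_d, n_j, n_c, n_transcripts)
LOCUS_DESIGNS = {
    "IGH": (20, 20, 6, 4, 50),
    "IGK": (20, 0, 6, 2, 50),
    "TRA": (15, 0, 8, 2, 40),
    "TRB": (15, 3, 8, 2, 40),
}


def run_benchmark(
    locus: str,
    platform: str = "pacbio_like",
    seed: int = 1,
    coverage: float = 20.0,
    mutation_rate: float = 1e-4,
    design: Optional[tuple[int, int, int, int, int]] = None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Simulate, annotate and score one locus; returns per-class segment
    metrics and the recombination-tuple metrics (VDJ where the locus has D
    segments, VJ otherwise)."""
    n_v, n_d, n_j, n_c, n_transcripts = design or LOCUS_DESIGNS[locus]
    db = make_synthetic_germline_db(n_v, n_d, n_j, n_c, locus=locus, seed=seed)
    cfg = SimConfig(
        seed=seed, coverage=coverage, platform=platform, mutation_rate=mutation_rate
    )
    transcripts, truth = simulate_repertoire(db, n_transcripts, cfg)
    sim_reads, truth = simulate_reads(transcripts, cfg, truth)
    records = [ReadRecord(r.read_id, r.sequence) for r in sim_reads]
    result = annotate_reads(records, db, config or PipelineConfig())
    calls = rearrangements_to_frame(result.rearrangements)
    segments = score_segments(calls, truth, mode="gene_set")
    recombination = score_recombinations(calls, truth, with_d=n_d > 0, mode="gene_set")
    return {
        "locus": locus,
        "platform": platform,
        "n_reads": len(records),
        "n_transcripts": n_transcripts,
        "segments": segments,
        "recombination": recombination,
        "with_d": n_d > 0,
    }
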