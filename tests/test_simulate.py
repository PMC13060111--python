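import math

import edlib
import numpy as np
import pytest
from scipy import stats

from vdjseq.cdr import translate
from vdjseq.simulate import (
    SimConfig,
    make_synthetic_germline_db,
    read_truth,
    simulate_reads,
    simulate_repertoire,
    write_truth,
)


def _global_identity(a, b):
    return 1 - edlib.align(a, b, task="distance")["editDistance"] / max(len(a), len(b))


class TestGermlineGenerator:
    def test_determinism(self, tmp_path):
        a = make_synthetic_germline_db(5, 4, 3, 2, locus="IGH", seed=3)
        b = make_synthetic_germline_db(5, 4, 3, 2, locus="IGH", seed=3)
        pa, pb = tmp_path / "a.fasta", tmp_path / "b.fasta"
        a.write_fasta(pa)
        b.write_fasta(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_pairwise_divergence_of_v_segments(self):
        db = make_synthetic_germline_db(20, 1, 1, 0, locus="IGH", seed=4)
        vs = [s.sequence for s in db.segments("IGH", "V")]
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                assert _global_identity(vs[i], vs[j]) < 0.80

    def test_planted_anchor_structure(self, igh_db):
        for v in igh_db.segments("IGH", "V"):
            aa = translate(v.sequence)
            assert aa[22] == "C"  # IMGT position 23
            assert aa[40] == "W"  # position 41
            assert aa[101:104] == aa[101] + aa[102] + "C" and aa[101] == aa[102] == "Y"
        for j in igh_db.segments("IGH", "J"):
            aaj = translate(j.sequence[j.frame_offset :])
            assert aaj[2] in "WF" and aaj[3] == "G" and aaj[5] == "G"

    def test_segment_length_ranges(self, igh_db):
        for d in igh_db.segments("IGH", "D"):
            assert 12 <= len(d.sequence) <= 30
        for c in igh_db.segments("IGH", "C"):
            assert 300 <= len(c.sequence) <= 600


class TestRepertoire:
    def test_exact_concatenation_without_noise(self, igh_db):
        cfg = SimConfig(
            seed=1,
            mutation_rate=0.0,
            rc_fraction=0.0,
            v_trim_max=0,
            j_trim_max=0,
            d_trim_max=0,
            n_insert_max=0,
        )
        transcripts, truth = simulate_repertoire(igh_db, 5, cfg)
        for tid, seq in transcripts.items():
            t = truth.transcripts[tid]
            expected = (
                igh_db.get(t.v).sequence
                + igh_db.get(t.d).sequence
                + igh_db.get(t.j).sequence
                + igh_db.get(t.c).sequence
            )
            assert seq == expected

    def test_half_reverse_complemented(self, igh_db):
        cfg = SimConfig(seed=2, rc_fraction=0.5)
        _, truth = simulate_repertoire(igh_db, 100, cfg)
        strands = [t.strand for t in truth.transcripts.values()]
        assert strands.count("-") == 50

    def test_mutation_count_within_binomial_interval(self, igh_db):
        cfg = SimConfig(seed=3, mutation_rate=1e-4, rc_fraction=0.0)
        transcripts, truth = simulate_repertoire(igh_db, 100, cfg)
        total_bases = sum(len(s) for s in transcripts.values())
        total_mut = sum(len(t.mutation_positions) for t in truth.transcripts.values())
        lo, hi = stats.binom.interval(0.99, total_bases, 1e-4)
        assert lo <= total_mut <= hi

    def test_truth_refers_to_database_segments(self, igh_db):
        cfg = SimConfig(seed=4)
        _, truth = simulate_repertoire(igh_db, 30, cfg)
        for t in truth.transcripts.values():
            assert t.v in igh_db and t.j in igh_db
            if t.d is not None:
                assert t.d in igh_db

    def test_light_chain_has_no_d(self, tra_db):
        cfg = SimConfig(seed=5)
        _, truth = simulate_repertoire(tra_db, 10, cfg)
        assert all(t.d is None for t in truth.transcripts.values())

    def test_every_v_used(self, igh_db):
        cfg = SimConfig(seed=6)
        _, truth = simulate_repertoire(igh_db, 16, cfg)
        used = {t.v for t in truth.transcripts.values()}
        assert used == {s.segment_id for s in igh_db.segments("IGH", "V")}


class TestReads:
    def test_error_free_reads_are_substrings(self, igh_db):
        cfg = SimConfig(seed=7, mutation_rate=0.0, coverage=2.0, pacbio_accuracy=(1.0, 1.0))
        transcripts, truth = simulate_repertoire(igh_db, 5, cfg)
        reads, truth = simulate_reads(transcripts, cfg, truth)
        for r in reads:
            assert r.sequence in transcripts[r.transcript_id]

    def test_coverage_accounting(self):
        db = make_synthetic_germline_db(2, 2, 2, 1, locus="IGH", seed=8)
        cfg = SimConfig(seed=8, coverage=20.0, mutation_rate=0.0)
        transcripts, truth = simulate_repertoire(db, 1, cfg)
        reads, _ = simulate_reads(transcripts, cfg, truth)
        L = len(next(iter(transcripts.values())))
        total = sum(len(r.sequence) for r in reads)
        assert abs(total - 20 * L) <= 0.1 * 20 * L

    def test_coverage_ratio_10_vs_40(self, igh_db):
        t, truth = simulate_repertoire(igh_db, 3, SimConfig(seed=9))
        lo, _ = simulate_reads(t, SimConfig(seed=9, coverage=10.0))
        hi, _ = simulate_reads(t, SimConfig(seed=9, coverage=40.0))
        ratio = sum(len(r.sequence) for r in hi) / sum(len(r.sequence) for r in lo)
        assert abs(ratio - 4.0) <= 0.4

    def test_fixed_seed_reproducibility(self, igh_db):
        cfg = SimConfig(seed=10, coverage=3.0)
        t1, tr1 = simulate_repertoire(igh_db, 5, cfg)
        r1, _ = simulate_reads(t1, cfg, tr1)
        t2, tr2 = simulate_repertoire(igh_db, 5, cfg)
        r2, _ = simulate_reads(t2, cfg, tr2)
        assert [(a.read_id, a.sequence, a.quality) for a in r1] == [
            (b.read_id, b.sequence, b.quality) for b in r2
        ]

    def test_pacbio_error_rate_within_band(self, igh_db):
        """Realized per-base error of the batch sits near the 1% mixture mean."""
        cfg = SimConfig(seed=11, coverage=10.0, mutation_rate=0.0)
        transcripts, truth = simulate_repertoire(igh_db, 5, cfg)
        reads, truth = simulate_reads(transcripts, cfg, truth)
        total_errors = sum(len(truth.reads[r.read_id].error_positions) for r in reads)
        total_bases = sum(len(r.sequence) for r in reads)
        rate = total_errors / total_bases
        assert 0.0 < rate < 0.02
        assert abs(rate - 0.01) < 0.004

    def test_nanopore_reads_truncate_to_transcript(self, igh_db):
        cfg = SimConfig(seed=12, platform="nanopore_like", coverage=3.0, mutation_rate=0.0)
        transcripts, truth = simulate_repertoire(igh_db, 4, cfg)
        reads, _ = simulate_reads(transcripts, cfg, truth)
        for r in reads:
            # ~1% indels: length stays within a few percent of the transcript
            assert len(r.sequence) <= 1.05 * len(transcripts[r.transcript_id])


class TestTruthIO:
    def test_round_trip(self, tmp_path, igh_db):
        cfg = SimConfig(seed=13, coverage=2.0)
        transcripts, truth = simulate_repertoire(igh_db, 5, cfg)
        _, truth = simulate_reads(transcripts, cfg, truth)
        p = tmp_path / "truth.tsv"
        write_truth(truth, p)
        back = read_truth(p)
        assert back.transcripts == truth.transcripts
        assert back.reads == truth.reads

    def test_empty_truth(self, tmp_path):
        from vdjseq.simulate import SimTruth

        p = tmp_path / "empty.tsv"
        write_truth(SimTruth(), p)
        assert p.read_text().count("\n") == 1
        back = read_truth(p)
        assert back.transcripts == {} and back.reads == {}

    def test_row_count(self, tmp_path, igh_db):
        cfg = SimConfig(seed=14, coverage=2.0)
        transcripts, truth = simulate_repertoire(igh_db, 4, cfg)
        reads, truth = simulate_reads(transcripts, cfg, truth)
        p = tmp_path / "t.tsv"
        write_truth(truth, p)
        n_rows = p.read_text().count("\n") - 1
        assert n_rows == len(reads) + 4


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(rc_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(mutation_rate=1.0)
    with pytest.raises(ValueError):
        SimConfig(coverage=0)
    with pytest.raises(ValueError):
        SimConfig(platform="illumina")
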