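import random

import pytest

from vdjseq.align import LocalHit, ScoringScheme, revcomp
from vdjseq.assign import (
    AssignmentThresholds,
    assign_read,
    recover_vdj_sequence,
    select_best_call,
)
from vdjseq.candidates import ReadRecord
from vdjseq.simulate import SimConfig, simulate_reads, simulate_repertoire

SCHEME = ScoringScheme()
T = AssignmentThresholds()


def _hit(segment_id="IGHV1*01", score=400, identity=99.0, length=300):
    return LocalHit(
        read_id="r",
        segment_id=segment_id,
        raw_score=score,
        identity_pct=identity,
        aligned_length=length,
        q_start=0,
        q_end=length,
        seg_start=0,
        seg_end=length,
        strand="+",
        read_len=1000,
    )


class TestSelectBestCall:
    def test_identity_floor_is_exclusive_below_90(self):
        assert select_best_call([_hit(identity=89.9)], "V", T) is None
        assert select_best_call([_hit(identity=90.0)], "V", T) is not None

    def test_score_tie_broken_by_identity(self):
        a = _hit("IGHV1*01", score=400, identity=98.0)
        b = _hit("IGHV2*01", score=400, identity=95.0)
        assert select_best_call([b, a], "V", T).segment_id == "IGHV1*01"

    def test_v_score_floor_applies_only_to_v(self):
        v349 = _hit(score=349, identity=99.0)
        assert select_best_call([v349], "V", T) is None
        j60 = _hit("IGHJ1*01", score=60, identity=99.0, length=30)
        assert select_best_call([j60], "J", T) is not None

    def test_full_tie_falls_back_to_segment_id(self):
        a = _hit("IGHV2*01")
        b = _hit("IGHV1*01")
        assert select_best_call([a, b], "V", T).segment_id == "IGHV1*01"

    def test_empty_input(self):
        assert select_best_call([], "V", T) is None

    def test_raising_identity_floor_is_monotone(self):
        hits = [_hit(identity=i) for i in (91.0, 94.0, 97.0)]
        n_calls = [
            select_best_call(hits, "J", AssignmentThresholds(min_identity_pct=thr)) is not None
            for thr in (90, 95, 99)
        ]
        assert n_calls == sorted(n_calls, reverse=True)


def _planted_read(db, rng, with_c=True):
    v = db.segments("IGH", "V")[rng.randrange(len(db.segments("IGH", "V")))]
    d = db.segments("IGH", "D")[rng.randrange(len(db.segments("IGH", "D")))]
    j = db.segments("IGH", "J")[rng.randrange(len(db.segments("IGH", "J")))]
    c = db.segments("IGH", "C")[0]
    seq = v.sequence + "AC" + d.sequence + "GT" + j.sequence
    if with_c:
        seq += c.sequence
    return ReadRecord("planted", seq), v, d, j, (c if with_c else None)


def test_assign_read_planted_truth(igh_db):
    rng = random.Random(0)
    read, v, d, j, c = _planted_read(igh_db, rng)
    asn = assign_read(read, igh_db, SCHEME, T)
    assert asn.call("V") == v.segment_id
    assert asn.call("D") == d.segment_id
    assert asn.call("J") == j.segment_id
    assert asn.call("C") == c.segment_id
    assert asn.orientation == "+"
    assert asn.locus == "IGH"


def test_assign_read_reverse_complement_strand(igh_db):
    rng = random.Random(1)
    read, v, d, j, c = _planted_read(igh_db, rng)
    rc_read = ReadRecord("rc", revcomp(read.sequence))
    asn = assign_read(rc_read, igh_db, SCHEME, T)
    assert asn.orientation == "-"
    assert asn.call("V") == v.segment_id
    assert asn.call("J") == j.segment_id
    assert asn.sequence_oriented == read.sequence


def test_assign_read_c_only(igh_db):
    c = igh_db.segments("IGH", "C")[1]
    asn = assign_read(ReadRecord("conly", c.sequence), igh_db, SCHEME, T)
    assert asn.call("C") == c.segment_id
    assert asn.call("V") is None and asn.call("J") is None and asn.call("D") is None


def test_assign_read_nothing_callable(igh_db):
    asn = assign_read(ReadRecord("junk", "ACGT" * 10), igh_db, SCHEME, T)
    assert asn is None


def test_d_detection_in_adjacent_vj_window(igh_db):
    """Even a zero-length V-J interval is searched with the 20 bp pad."""
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    read = ReadRecord("adj", v.sequence + j.sequence)
    asn = assign_read(read, igh_db, SCHEME, T)
    assert asn.call("V") == v.segment_id and asn.call("J") == j.segment_id
    # no planted D: any D call would have to clear >80% identity inside the pad
    if asn.d is not None:
        assert asn.d.hit.identity_pct > 80.0


def test_d_below_identity_floor_left_uncalled(igh_db):
    rng = random.Random(2)
    v = igh_db.segments("IGH", "V")[0]
    d = igh_db.segments("IGH", "D")[0]
    j = igh_db.segments("IGH", "J")[0]
    # scramble the D so no database D reaches 80% identity in the window
    scrambled = "".join(rng.choice("ACGT") for _ in d.sequence)
    read = ReadRecord("mut", v.sequence + "AC" + scrambled + "GT" + j.sequence)
    asn = assign_read(read, igh_db, SCHEME, T)
    if asn.d is not None:
        assert asn.d.hit.identity_pct > 80.0


def test_recover_vdj_sequence_spans_junction(igh_db):
    rng = random.Random(3)
    read, v, d, j, c = _planted_read(igh_db, rng)
    asn = assign_read(read, igh_db, SCHEME, T)
    vdj = recover_vdj_sequence(asn)
    assert d.sequence in vdj
    assert vdj in read.sequence
    assert vdj.startswith(v.sequence[:50])

    with pytest.raises(ValueError):
        recover_vdj_sequence(
            assign_read(ReadRecord("conly", igh_db.segments("IGH", "C")[0].sequence), igh_db)
        )


def test_no_emitted_call_violates_thresholds(igh_db):
    cfg = SimConfig(seed=21, coverage=2.0)
    transcripts, truth = simulate_repertoire(igh_db, 8, cfg)
    reads, _ = simulate_reads(transcripts, cfg, truth)
    for r in reads[:20]:
        asn = assign_read(ReadRecord(r.read_id, r.sequence), igh_db, SCHEME, T)
        if asn is None:
            continue
        for cls in ("V", "J", "C"):
            sc = asn.slot(cls)
            if sc is None:
                continue
            assert sc.hit.identity_pct >= T.min_identity_pct
            if cls == "V":
                assert sc.hit.raw_score >= T.min_v_score
        if asn.d is not None:
            assert asn.d.hit.identity_pct > T.d_min_identity_pct


def test_determinism(igh_db):
    rng = random.Random(5)
    read, *_ = _planted_read(igh_db, rng)
    a1 = assign_read(read, igh_db, SCHEME, T)
    a2 = assign_read(read, igh_db, SCHEME, T)
    assert a1.combination() == a2.combination()
    assert (a1.v.start, a1.v.end, a1.j.start, a1.j.end) == (
        a2.v.start,
        a2.v.end,
        a2.j.start,
        a2.j.end,
    )


def test_thresholds_validation():
    with pytest.raises(ValueError):
        AssignmentThresholds(min_identity_pct=101)
    with pytest.raises(ValueError):
        AssignmentThresholds(vj_pad=-1)
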