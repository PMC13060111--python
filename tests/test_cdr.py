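import pytest

from vdjseq.align import ScoringScheme
from vdjseq.assign import AssignmentThresholds, assign_read
from vdjseq.candidates import ReadRecord
from vdjseq.cdr import CdrRuleSet, annotate_rearrangement, locate_cdr3, translate
from vdjseq.germline import GermlineDatabase, GermlineSegment
from vdjseq.simulate import SimConfig, simulate_reads, simulate_repertoire

SCHEME = ScoringScheme()
T = AssignmentThresholds()


@pytest.mark.parametrize(
    "nt,frame,expected",
    [
        ("TATTACTGT", 0, "YYC"),
        ("ATGTAA", 0, "M*"),
        ("AATGTAA", 1, "M*"),
        ("ATGAA", 0, "M"),  # trailing partial codon dropped
        ("ATGNNT", 0, "MX"),  # ambiguous codon
        ("TGGGGCCAAGGG", 0, "WGQG"),
    ],
)
def test_translate(nt, frame, expected):
    assert translate(nt, frame) == expected


def test_translate_rejects_bad_frame():
    with pytest.raises(ValueError):
        translate("ACGT", 3)


def _assign(read_seq, db):
    return assign_read(ReadRecord("r", read_seq), db, SCHEME, T)


def test_cdr3_planted_anchors(igh_db):
    """Hand-planted junction: V ends ...YYC, J starts with its [WF]GxG motif
    downstream; the extracted CDR3 is anchor-inclusive."""
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    # junction length chosen so the J terminus stays in frame with the V anchor
    junction = "GGTACCAAA" + "A" * ((3 - j.frame_offset) % 3)
    read = v.sequence + junction + j.sequence + igh_db.segments("IGH", "C")[0].sequence
    asn = _assign(read, igh_db)
    start, end, reason = locate_cdr3(asn, v, j, CdrRuleSet())
    assert reason is None
    cdr3 = read[start:end]
    # starts at the conserved C codon (position 104 = codon 103 at frame 0)
    assert start == 309
    aa = translate(cdr3)
    assert aa[0] == "C"
    assert aa[-1] in "WF"
    assert junction in cdr3


def test_cdr3_fallback_to_position_104(igh_db):
    """Removing YYC from the V switches the start rule to IMGT position 104."""
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    # mutate the two Y codons (101, 102) so the motif is gone but position
    # 104 still holds its cysteine codon
    s = list(v.sequence)
    s[303:306] = "GCT"  # codon 101 -> A
    s[306:309] = "GCT"  # codon 102 -> A
    v2 = GermlineSegment("IGHV98*01", "IGH", "V", "IGHV98", "01", "".join(s))
    db2 = GermlineDatabase(
        [v2, j] + igh_db.segments("IGH", "C") + igh_db.segments("IGH", "D")
    )
    read = v2.sequence + "GGTACCAAA" + j.sequence
    asn = _assign(read, db2)
    start, end, reason = locate_cdr3(asn, v2, j, CdrRuleSet())
    assert reason is None
    assert start == 309  # codon index 103 = IMGT position 104
    assert translate(read[start : start + 3]) == "C"


def test_cdr3_missing_j_terminus(igh_db):
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    # destroy the J motif tryptophan
    s = list(j.sequence)
    k = translate(j.sequence[j.frame_offset :]).find("W")
    pos = j.frame_offset + 3 * k
    s[pos : pos + 3] = "GCT"
    j2 = GermlineSegment("IGHJ98*01", "IGH", "J", "IGHJ98", "01", "".join(s), j.frame_offset)
    db2 = GermlineDatabase([v, j2] + igh_db.segments("IGH", "C"))
    read = v.sequence + "GGTACCAAA" + j2.sequence
    asn = _assign(read, db2)
    start, end, reason = locate_cdr3(asn, v, j2, CdrRuleSet())
    assert (start, end) == (None, None)
    assert reason == "no_j_anchor"


def test_cdr1_cdr2_planted_positions(igh_db):
    """A read identical to the germline V yields CDR1 = positions 27-38 and
    CDR2 = 56-65 of the germline translation, with valid anchors."""
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    read = v.sequence + "GGTACCAAA" + j.sequence
    asn = _assign(read, igh_db)
    r = annotate_rearrangement(asn, igh_db)
    germ_aa = translate(v.sequence)
    assert r.cdr.cdr1_aa == germ_aa[26:38]
    assert r.cdr.cdr2_aa == germ_aa[55:65]
    assert r.cdr.anchors_valid == {"c23": True, "w41": True}
    assert len(r.cdr.cdr1_nt) == 36 and len(r.cdr.cdr2_nt) == 30


def test_cdr1_absent_when_alignment_starts_inside(igh_db):
    """V alignment starting at germline aa ~30 leaves CDR1 uncovered but CDR2 intact."""
    v = igh_db.segments("IGH", "V")[0]
    j = igh_db.segments("IGH", "J")[0]
    read = v.sequence[90:] + "GGTACCAAA" + j.sequence  # drop first 30 codons
    asn = _assign(read, igh_db)
    r = annotate_rearrangement(asn, igh_db)
    assert r.cdr.cdr1_nt is None
    assert r.cdr.cdr2_aa == translate(v.sequence)[55:65]


def test_bad_anchor_reported_but_regions_kept(igh_db):
    v = igh_db.segments("IGH", "V")[0]
    s = list(v.sequence)
    s[120:123] = "GCT"  # position 41 codon -> A instead of W
    v2 = GermlineSegment("IGHV97*01", "IGH", "V", "IGHV97", "01", "".join(s))
    j = igh_db.segments("IGH", "J")[0]
    db2 = GermlineDatabase([v2, j] + igh_db.segments("IGH", "C"))
    read = v2.sequence + "GGTACCAAA" + j.sequence
    r = annotate_rearrangement(_assign(read, db2), db2)
    assert r.cdr.anchors_valid["w41"] is False
    assert r.cdr.anchors_valid["c23"] is True
    assert r.cdr.cdr2_nt is not None


def test_cdr3_nt_substring_and_frame_invariants(igh_db):
    """On simulated reads every CDR3 is a substring of the oriented read;
    in-frame CDR3s translate consistently."""
    cfg = SimConfig(seed=9, mutation_rate=0.0, coverage=2.0, pacbio_accuracy=(1.0, 1.0))
    transcripts, truth = simulate_repertoire(igh_db, 10, cfg)
    reads, truth = simulate_reads(transcripts, cfg, truth)
    n_with_cdr3 = 0
    for sr in reads[:20]:
        asn = assign_read(ReadRecord(sr.read_id, sr.sequence), igh_db, SCHEME, T)
        if asn is None:
            continue
        r = annotate_rearrangement(asn, igh_db)
        if r.cdr.cdr3_nt is None:
            continue
        n_with_cdr3 += 1
        assert r.cdr.cdr3_nt in asn.sequence_oriented
        assert asn.v.start <= r.cdr.cdr3_read_start < r.cdr.cdr3_read_end <= asn.j.end
        if r.cdr.cdr3_aa is not None:
            assert len(r.cdr.cdr3_nt) == 3 * len(r.cdr.cdr3_aa)
            assert r.cdr.cdr3_aa == translate(r.cdr.cdr3_nt)
            assert r.cdr.cdr3_aa[0] == "C" and r.cdr.cdr3_aa[-1] in "WF"
    assert n_with_cdr3 >= 10


def test_c_only_read_has_empty_cdrs(igh_db):
    c = igh_db.segments("IGH", "C")[0]
    asn = _assign(c.sequence, igh_db)
    r = annotate_rearrangement(asn, igh_db)
    assert r.cdr.cdr1_nt is None and r.cdr.cdr3_nt is None
    assert r.vdj_sequence is None


def test_ruleset_validation():
    with pytest.raises(ValueError):
        CdrRuleSet(cdr1_range=(38, 27))
    with pytest.raises(ValueError):
        CdrRuleSet(cdr3_fallback_position=60)
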