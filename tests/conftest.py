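import warnings

import pytest

from vdjseq.candidates import ReadRecord
from vdjseq.simulate import SimConfig, make_synthetic_germline_db, simulate_reads, simulate_repertoire

warnings.filterwarnings("ignore", message="transcript shorter")


@pytest.fixture(scope="session")
def igh_db():
    """Small IGH-like germline set with planted anchors, pairwise-divergent."""
    return make_synthetic_germline_db(8, 6, 4, 3, locus="IGH", seed=42)


@pytest.fixture(scope="session")
def tra_db():
    return make_synthetic_germline_db(6, 0, 4, 2, locus="TRA", seed=43)


@pytest.fixture(scope="session")
def clean_bundle(igh_db):
    """Error-free reads with truth: 15 transcripts at 3x, no mutations."""
    cfg = SimConfig(seed=7, mutation_rate=0.0, coverage=3.0, pacbio_accuracy=(1.0, 1.0))
    transcripts, truth = simulate_repertoire(igh_db, 15, cfg)
    reads, truth = simulate_reads(transcripts, cfg, truth)
    records = [ReadRecord(r.read_id, r.sequence) for r in reads]
    return igh_db, transcripts, records, truth
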