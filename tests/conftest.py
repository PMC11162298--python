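import numpy as np
import pytest

from dasv.alignment_io import AlignmentRecord, qc_filter
from dasv.synthetic_data import SimConfig, simulate


def make_record(pos=1, cigar=(("M", 100),),
                name="r1", chrom="chr1", mapq=60, flag=0, seq=None):
    """A hand-built alignment record for unit tests (1-based pos)."""
    cigar = tuple(cigar)
    if seq is None:
        qlen = sum(n for op, n in cigar if op in "MIS=X")
        seq = "A" * qlen
    return AlignmentRecord(query_name=name, flag=flag, ref_name=chrom,
                           pos=pos, mapq=mapq, cigar=cigar, seq=seq)


@pytest.fixture(scope="session")
def small_sim():
    """A compact homozygous simulation reused by several unit tests."""
    cfg = SimConfig(ref_length=150_000, n_deletions=5,
                    size_ranges=[(50, 800)], depth=25, seed=11)
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def small_records(small_sim):
    _cfg, res = small_sim
    return list(qc_filter(res.records))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
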