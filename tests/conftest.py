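import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stacktail.alignment_io import AlignedRead

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_read(
    read_id="r1",
    chrom="chr1",
    ref_start=1000,
    cigar=((100, "M"),),
    seq=None,
    quals=None,
    **kw,
):
    """Build a consistent AlignedRead from a cigar given as (length, op) pairs."""
    cig = [(op, n) for n, op in cigar]
    qlen = sum(n for op, n in cig if op in "MIS=X")
    rng = np.random.default_rng(abs(hash(read_id)) % 2**31)
    if seq is None:
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, qlen)])
    if quals is None:
        quals = [35] * len(seq)
    return AlignedRead(read_id, chrom, ref_start, cig, seq, quals, **kw)


@pytest.fixture
def small_reference():
    """Two deterministic 2-kb chromosomes."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {c: "".join(bases[rng.integers(0, 4, 2000)]) for c in ("chr1", "chr2")}
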