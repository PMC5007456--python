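import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kiwitx.transcript_model import ASSEMBLED, GenomicInterval, Transcript

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_tx(tid, exons, strand="+", seq_id="chr1", gene_id=None, source=ASSEMBLED):
    """Build a Transcript from (start, end) pairs."""
    return Transcript(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        exons=[GenomicInterval(seq_id, s, e, strand) for s, e in exons],
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20161020)
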