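import numpy as np
import pytest
from hypothesis import settings

from asdetect.splice_model import ExonRecord, build_splice_graph

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def three_exon_gene():
    """Single-transcript gene E1-E2-E3 on the + strand."""
    return build_splice_graph(
        [
            ExonRecord("geneX", "tx1", "chrI", 100, 200, "+"),
            ExonRecord("geneX", "tx1", "chrI", 300, 400, "+"),
            ExonRecord("geneX", "tx1", "chrI", 500, 600, "+"),
        ]
    )


@pytest.fixture
def cassette_gene():
    """Gene with isoforms E1-E2-E3 and E1-E3: one annotated skipping junction."""
    records = [
        ExonRecord("geneY", "tx1", "chrI", 100, 200, "+"),
        ExonRecord("geneY", "tx1", "chrI", 300, 400, "+"),
        ExonRecord("geneY", "tx1", "chrI", 500, 600, "+"),
        ExonRecord("geneY", "tx2", "chrI", 100, 200, "+"),
        ExonRecord("geneY", "tx2", "chrI", 500, 600, "+"),
    ]
    return build_splice_graph(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
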