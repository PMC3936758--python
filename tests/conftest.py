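import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

import grostitch as gs


@pytest.fixture(scope="session")
def default_scenario():
    """Default synthetic scenario at nominal depth (one shared simulation)."""
    model = gs.default_model(seed=0)
    tags, truth = gs.simulate_reads(model)
    return model, tags, truth


@pytest.fixture(scope="session")
def deep_scenario():
    """Default scenario at high depth: every feature >= 10x read coverage."""
    model = gs.default_model(seed=0, depth=12)
    tags, truth = gs.simulate_reads(model)
    return model, tags, truth


def make_proto(start, end, count=1, chrom="chr1", strand="+", sample="A"):
    return gs.ProtoTranscript(chrom, strand, start, end, {sample: count})


def make_transcript(start, end, tid="T0", chrom="chr1", strand="+",
                    counts=None, **kw):
    return gs.Transcript(tid, chrom, strand, start, end, counts or {"A": 10}, **kw)
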