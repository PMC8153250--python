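import numpy as np
import pytest

from lutiscan.clustering import CtssPosition
from lutiscan.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """Full-size noiseless synthetic study, shared across tests."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_calls(default_study):
    from lutiscan.pipeline import run_discovery

    calls, promoters = run_discovery(default_study)
    return calls, promoters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_positions(rng, n, chroms=("chr1",), strands=("+", "-"), max_pos=500, samples=("s1",)):
    """Random CTSS instance with unique (chrom, pos, strand) keys."""
    seen = set()
    out = []
    while len(out) < n:
        chrom = chroms[rng.integers(len(chroms))]
        strand = strands[rng.integers(len(strands))]
        pos = int(rng.integers(0, max_pos))
        key = (chrom, pos, strand)
        if key in seen:
            continue
        seen.add(key)
        tpm = {s: float(rng.uniform(0, 5)) for s in samples}
        out.append(CtssPosition(chrom, pos, strand, counts=dict(tpm), tpm=tpm))
    return out
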