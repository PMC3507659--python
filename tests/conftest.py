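import numpy as np
import pytest

from spmgraph import simdata
from spmgraph.pipeline import PipelineConfig
from spmgraph.readset import Read


@pytest.fixture
def trio_reads():
    """Three reads chaining r -> s -> t with a transitive shortcut r -> t."""
    return [Read(1, "TGGACGT"), Read(2, "GGACGTAA"), Read(3, "ACGTAACC")]


@pytest.fixture
def trio_cfg():
    """Forward-only small-k configuration matching the hand-computed trio."""
    return PipelineConfig(
        l_min=4, k=4, k_prime=4, k_dbl_prime=3, both_strands=False, min_contig_length=1
    )


def simulated_read_set(seed: int, l_min: int, coverage: float = 6.0,
                       template_range=(300, 1500), length_range=(30, 120)):
    """A small overlapping read set sampled from a random template."""
    rng = np.random.default_rng(seed)
    tlen = int(rng.integers(*template_range))
    template = simdata.random_genome(tlen, rng)
    lo = max(length_range[0], l_min + 5)
    cfg = simdata.SimConfig(
        template_length=tlen,
        coverage=coverage,
        read_length=(lo, max(lo, length_range[1])),
        seed=seed + 10_000,
    )
    return template, simdata.simulate_reads(template, cfg)
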