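import numpy as np
import pytest

import dupscape as d


@pytest.fixture
def genome():
    return d.GenomeIndex([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated study shared by read-only tests."""
    cfg = d.SimConfig(
        seed=11, n_chromosomes=5, mean_chrom_length=2_500_000, n_loci=120
    )
    return d.simulate_all(cfg)


def random_ci_calls(rng, n, chrom="chr1", chrom_len=1_000_000, method="PE_SR"):
    """Random CICall instances for clustering property tests."""
    genome = d.GenomeIndex([(chrom, chrom_len)])
    calls = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 5000))
        size = int(rng.integers(200, 4000))
        calls.append(
            d.assign_breakpoint_ci(
                d.RawCall(chrom, start, start + size, method, f"s{i}",
                          support_pairs=5, support_mq=60, id=f"c{i}"),
                genome,
            )
        )
    return calls
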