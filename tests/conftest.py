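import numpy as np
import pandas as pd
import pytest

from dimorphatac import simulate as sim
from dimorphatac.intervals import GenomeSpec, GenomicInterval


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec([("chrX", 200_000, "X"), ("chr2", 300_000, "autosome")])


@pytest.fixture(scope="session")
def default_sim():
    """One shared default simulation (counts + truth), seed fixed."""
    config = sim.SimulationConfig(seed=2024)
    cm, truth = sim.simulate_counts(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def default_fragments(default_sim):
    config, cm, _ = default_sim
    return sim.simulate_fragments(config, cm)


def random_intervals(rng: np.random.Generator, n: int,
                     chroms=("chr2", "chr3", "chrX")) -> list[GenomicInterval]:
    out = []
    for i in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, 1_000_000))
        length = int(rng.integers(1, 5_000))
        out.append(GenomicInterval(chrom, start, start + length,
                                   name=f"iv{i}", score=float(rng.integers(0, 100)),
                                   strand=str(rng.choice(["+", "-", "."]))))
    return out
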