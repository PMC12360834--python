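import numpy as np
import pytest

from bishash.index import IndexParams, build_genome_index
from bishash.sim import assign_methylation, generate_reference, simulate_reads
from bishash.sketch import SketchConfig


def random_kmers(rng: np.random.Generator, n: int, k: int) -> set[str]:
    return {
        "".join("ACGT"[c] for c in rng.integers(0, 4, k)) for _ in range(n)
    }


def overlapping_kmer_pair(
    rng: np.random.Generator, k: int = 8, pool: int = 260, draw: int = 140
) -> tuple[set[str], set[str]]:
    """Two k-mer sets drawn from a shared pool, so their Jaccard is
    intermediate rather than degenerate."""
    universe = sorted(random_kmers(rng, pool, k))
    a = set(rng.choice(universe, size=min(draw, len(universe)), replace=False))
    b = set(rng.choice(universe, size=min(draw, len(universe)), replace=False))
    return a, b


@pytest.fixture(scope="session")
def toy_reference():
    """10 kb single-contig random reference."""
    return generate_reference(1, 10_000, 0.5, 0.0, seed=101)


@pytest.fixture(scope="session")
def toy_index(toy_reference):
    params = IndexParams(T=500, tau=300, sketch=SketchConfig(master_seed=7))
    return build_genome_index(toy_reference, params)


@pytest.fixture(scope="session")
def toy_reads(toy_reference):
    profile = assign_methylation(toy_reference, "random", seed=102)
    reads, truth = simulate_reads(
        toy_reference, profile, 60, read_len=150, error_rate=0.0, seed=103
    )
    return reads, truth
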