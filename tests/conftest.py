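import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from npstools.genome import ClusterSet, GenomeDef, GenomicInterval

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_genome() -> GenomeDef:
    """One 10 kb chromosome — small enough for per-base bitmap oracles."""
    return GenomeDef((("chr1", 10_000),))


@pytest.fixture
def two_chrom_genome() -> GenomeDef:
    return GenomeDef((("chr1", 10_000), ("chr2", 5_000)))


def random_intervals(rng: np.random.Generator, genome: GenomeDef, n: int, max_len: int = 500):
    """n random raw (possibly overlapping) intervals across the genome."""
    out = []
    names = genome.names
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        chrom_len = genome.length(chrom)
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_len - length + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def bitmap(intervals, genome: GenomeDef) -> dict[str, np.ndarray]:
    """Per-base boolean membership oracle."""
    maps = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.names}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps


def cluster_from(rng, genome, n, max_len=500, protein="X") -> ClusterSet:
    return ClusterSet.from_intervals(protein, random_intervals(rng, genome, n, max_len), genome)
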