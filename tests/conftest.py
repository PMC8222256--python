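import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import g4stress as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy_genome():
    """Two-chromosome assembly with explicit sequences."""
    seqs = {"chr1": "ACGT" * 25, "chr2": "TTTT" * 10}
    return g.GenomeAssembly(["chr1", "chr2"], {c: len(s) for c, s in seqs.items()}, seqs)


@pytest.fixture()
def sim_default():
    """Default synthetic dataset: genome + truth + peaks under one seed."""
    cfg = g.SimConfig(seed=11)
    rng = cfg.rng()
    genome, truth = g.make_genome(cfg, rng)
    peaks = g.make_peaks(genome, truth, cfg, rng)
    return cfg, genome, truth, peaks


def random_interval_set(rng: np.random.Generator, n: int, genome=None,
                        chroms=("chr1", "chr2"), max_pos=1000) -> g.IntervalSet:
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        end = int(rng.integers(start + 1, max_pos))
        ivs.append(g.Interval(chrom, start, end))
    return g.IntervalSet(ivs, genome)
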