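import numpy as np
import pandas as pd
import pytest

from crosscna.types import Chromosome, Genome, PlantedCnaSpec
from crosscna.synthetic_data import make_genome_pair, simulate_cohort


@pytest.fixture(scope="session")
def genome_pair():
    return make_genome_pair(seed=1, n_chrom=2, genes_per_chrom=50, ortholog_rate=1.0)


@pytest.fixture()
def tiny_genome():
    """Three genes on one 1 Mb chromosome, hand-placed."""
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chromosome": ["chr1"] * 3,
        "start": [100_000, 400_000, 700_000],
        "end": [200_000, 500_000, 800_000],
        "strand": ["+", "-", "+"],
    })
    return Genome([Chromosome("chr1", 1_000_000)], genes)


@pytest.fixture()
def noiseless_cohort(tiny_genome):
    spec = PlantedCnaSpec("chr1", 100_000, 500_000, "gain", 0.8, 1.0, "tumor",
                          spec_id="g1")
    profiles, truth = simulate_cohort(tiny_genome, [spec], {"tumor": 4},
                                      probe_spacing=50_000, noise_sd=0.0, seed=7)
    return profiles, truth, spec


def step_profile(n=100, cp=50, shift=1.0, sd=0.1, seed=0):
    """Single-change-point probe profile on one chromosome."""
    from crosscna.types import ProbeProfile

    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sd, n)
    x[cp:] += shift
    return ProbeProfile("s1", pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chromosome": "chr1",
        "position": np.arange(1, n + 1) * 1000,
        "log2_ratio": x,
    }))
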