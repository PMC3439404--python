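import numpy as np
import pytest

from dartmap import linkage_map as lm
from dartmap import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    spec = sd.SyntheticGenomeSpec(
        n_chromosomes=3,
        chromosome_lengths=[300_000, 300_000, 300_000],
        n_unanchored_scaffolds=4,
        unanchored_length_range=(5_000, 20_000),
        gene_density=30.0,
        seed=11,
    )
    return sd.simulate_genome(spec)


@pytest.fixture(scope="session")
def planted_probes(small_genome):
    return sd.plant_probes(
        small_genome, n_probes=120, redundancy_rate=0.3, mutation_rate=0.0, seed=12
    )


@pytest.fixture(scope="session")
def noisy_cross():
    """Three-chromosome cross at the reference noise settings."""
    lengths = {f"Chr{i + 1:02d}": 45_000_000 for i in range(3)}
    spec = sd.CrossSimSpec(
        n_progeny=177,
        markers_per_chromosome=100,
        missing_rate=0.10,
        error_rate=0.01,
        kbp_per_cm_truth=500.0,
        seed=21,
    )
    return sd.simulate_cross(lengths, spec)


@pytest.fixture(scope="session")
def noisy_two_point(noisy_cross):
    return lm.two_point_table(
        noisy_cross.genotypes, noisy_cross.truth["seg_type"], error_rate=0.01
    )


@pytest.fixture(scope="session")
def clean_cross():
    lengths = {f"Chr{i + 1:02d}": 30_000_000 for i in range(3)}
    spec = sd.CrossSimSpec(
        n_progeny=177,
        markers_per_chromosome=60,
        missing_rate=0.0,
        error_rate=0.0,
        kbp_per_cm_truth=500.0,
        seed=22,
    )
    return sd.simulate_cross(lengths, spec)
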