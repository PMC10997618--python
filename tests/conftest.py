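"""Shared fixtures.

The expensive end-to-end runs (the standard 50-kb diploid condition, the
repeat fixture, and the homozygous fixture) are session-scoped so the whole
suite pays for each of them once.
"""

import numpy as np
import pytest

from diphase.pipeline import PipelineConfig, run_pipeline
from diphase.simdata import SimParams, simulate_diploid_genome, simulate_reads


@pytest.fixture(scope="session")
def diploid_run():
    """Full pipeline under the standard study conditions: 50-kb genome,
    1% SNP heterozygosity, 10% read error, 40x per haplotype."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def repeat_run():
    """Near-identical repeat scenario: 2-kb unit, 2 copies, 0.5% divergence,
    homozygous background, reads too short to span the repeat."""
    sim = SimParams(
        genome_length=20_000, het_rate=0.0, depth_per_haplotype=25,
        read_length_mean=1200, read_length_sd=300, error_rate=0.10,
        repeat_spec=[(2000, 2, 0.005)], seed=2,
    )
    return run_pipeline(PipelineConfig(sim=sim, seed=2))


@pytest.fixture(scope="session")
def homozygous_run():
    """Zero-heterozygosity control: the dual assembly must fall back to a
    single haplotype set."""
    sim = SimParams(
        genome_length=20_000, het_rate=0.0, depth_per_haplotype=20, seed=3
    )
    return run_pipeline(PipelineConfig(sim=sim, seed=3))


@pytest.fixture(scope="session")
def small_sim():
    """A small error-free diploid simulation for overlap/graph unit tests."""
    p = SimParams(
        genome_length=20_000, het_rate=0.0, depth_per_haplotype=12,
        read_length_mean=4000, read_length_sd=800, error_rate=0.0, seed=7,
    )
    haps, truth = simulate_diploid_genome(p)
    reads, truth = simulate_reads(haps, truth, p)
    return p, haps, truth, dict(reads)


@pytest.fixture(scope="session")
def noisy_sim():
    """A small noisy diploid simulation (1% het, 10% error) for correction
    unit tests."""
    p = SimParams(
        genome_length=15_000, het_rate=0.01, depth_per_haplotype=25,
        read_length_mean=4000, read_length_sd=800, error_rate=0.10, seed=11,
    )
    haps, truth = simulate_diploid_genome(p)
    reads, truth = simulate_reads(haps, truth, p)
    return p, haps, truth, dict(reads)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
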