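"""Shared fixtures: one default-condition simulated study per session plus
small fast genomes for unit-level work."""

import numpy as np
import pytest

from recessmap.pipeline import RunConfig, simulate_study
from recessmap.simcross import GenomeSpec, build_reference


@pytest.fixture(scope="session")
def small_spec() -> GenomeSpec:
    """Compact three-chromosome genome for unit tests."""
    return GenomeSpec(
        chromosomes=(("chr1", 2_000_000), ("chr2", 2_000_000), ("chr3", 2_000_000)),
        snp_density=1e-4,
        causal_gene_start=1_000_000,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return build_reference(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_config(small_spec) -> RunConfig:
    """Fast full-pipeline configuration (small genome, small cohorts)."""
    return RunConfig(seed=5, genome=small_spec, n_per_sampling=100, n_samplings=3)


@pytest.fixture(scope="session")
def study():
    """One simulated study at the default (study-condition) parameters."""
    return simulate_study(RunConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
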