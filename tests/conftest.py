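"""Shared fixtures: simulated studies at the scales the test suite uses.

Session scope keeps the expensive full-size study (8 strains x 20k pairs) to a
single simulation + analysis shared by the end-to-end tests.
"""

import pytest

from readtriage import SimulationConfig, analyze_study, simulate_study

FULL_SEED = 1


@pytest.fixture(scope="session")
def full_study():
    """Full-size error-free study: 8 strains, 20 000 unmapped pairs each."""
    return simulate_study(SimulationConfig(seed=FULL_SEED))


@pytest.fixture(scope="session")
def full_analysis(full_study):
    return analyze_study(full_study)


@pytest.fixture(scope="session")
def noisy_study():
    """Same conditions with 1% per-base sequencing error."""
    return simulate_study(SimulationConfig(seed=FULL_SEED, error_rate=0.01))


@pytest.fixture(scope="session")
def noisy_analysis(noisy_study):
    return analyze_study(noisy_study, do_similarity=False, do_contigs=False)


@pytest.fixture(scope="session")
def small_study():
    """Light study for unit-level planted-truth checks."""
    return simulate_study(
        SimulationConfig(seed=5, n_strains=4, n_pairs=1500, genome_length=200_000)
    )
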