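"""Shared fixtures: small synthetic genomes sized for fast tests."""

import numpy as np
import pytest

from cafskit.synthetic import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_truth():
    """A 3-chromosome, ~6-Mb genome with sequences (fast, reused read-only)."""
    cfg = SimulationConfig(
        seed=42,
        n_chromosomes=3,
        chrom_lengths=(2_500_000, 2_000_000, 1_500_000),
        ridge_blocks_per_chrom=1,
        ridge_span=400_000,
        scaffold_target_n50=300_000,
    )
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def positions_only_truth():
    """A 12-chromosome desk-scale genome without sequences (gene positions,
    tiling and anchors only; cheap enough for recovery tests)."""
    cfg = SimulationConfig(seed=7, generate_sequences=False)
    return simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
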