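"""Shared fixtures: a small and a default-scale synthetic dataset.

Everything is generated programmatically at test time; seeds are fixed so
the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from remodelseq.simulate import generate_genome, plant_loci


@pytest.fixture(scope="session")
def small_truth():
    """~120-locus genome for fast generator/recovery tests."""
    genome = generate_genome(n_chroms=2, chrom_len_bp=1_200_000, seed=101)
    genome, truth = plant_loci(genome, n_per_archetype=40, seed=102)
    return genome, truth


@pytest.fixture(scope="session")
def default_truth():
    """The generator's default study conditions: 2 x 2.5 Mb, 900 loci."""
    genome = generate_genome(seed=11)
    genome, truth = plant_loci(genome, n_per_archetype=300, seed=12)
    return genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
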