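"""Shared fixtures: tiny genomes, alphabets and synthetic compendia."""

import numpy as np
import pytest

from gecsi import BinnedGenome, StateAnnotation
from gecsi.synthetic import SimulationConfig, generate_compendium


@pytest.fixture
def tiny_genome():
    """Two chromosomes, 10 + 5 bins, last bin of chr2 shortened to 100 bp."""
    return BinnedGenome(
        chrom_names=("chr1", "chr2"), chrom_lengths=(2000, 900), bin_size=200
    )


@pytest.fixture
def abc_alphabet():
    return ("1_TssA", "2_TssFlnk", "3_TssFlnkU")


@pytest.fixture
def small_synth():
    """A small, fast synthetic compendium with 6 states and mild noise."""
    cfg = SimulationConfig(
        n_samples=12,
        n_groups=3,
        n_genes=120,
        n_bins=1200,
        n_states=6,
        annotation_noise=0.05,
        seed=11,
    )
    return generate_compendium(cfg)


def random_annotation(genome, alphabet, seed, missing_frac=0.0):
    """Helper used across test modules: a random StateAnnotation."""
    rng = np.random.default_rng(seed)
    states = rng.integers(0, len(alphabet), genome.n_bins).astype(np.int16)
    if missing_frac > 0:
        states[rng.random(genome.n_bins) < missing_frac] = -1
    return StateAnnotation(
        sample_id=f"rand{seed}", states=states, genome=genome, alphabet=alphabet
    )
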