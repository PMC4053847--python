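import numpy as np
import pytest

from transannot import SearchDatabase
from transannot.simulate import SimConfig, generate_reference, \
    generate_transcripts


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded synthetic experiment shared across test modules."""
    config = SimConfig(rng_seed=11, n_families=8,
                       n_clean_transcripts=25, n_indel_transcripts=25,
                       n_truncated_transcripts=8,
                       root_protein_length_range=(120, 300))
    reference = generate_reference(config)
    transcripts, truth = generate_transcripts(reference, config)
    return config, reference, transcripts, truth


@pytest.fixture(scope="session")
def small_sim_hits(small_sim):
    """Built-in-search hits for the small experiment (E <= 1e-5)."""
    _, reference, transcripts, _ = small_sim
    db = SearchDatabase(reference.proteins())
    return {t.id: db.search(t, evalue_cutoff=1e-5) for t in transcripts}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
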