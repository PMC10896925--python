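import numpy as np
import pytest

from cernaforge.synthetic_data import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study: 3 planted triplets, 4 samples/group."""
    return SimConfig(n_mrna=30, n_lncrna=12, n_mirna=15, n_per_group=4,
                     n_triplets=3, shared_mirnas_per_triplet=2,
                     mres_per_transcript=2, n_tf=3, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """(transcripts, counts, pfms, tf_gene_pairs, gene_sets, truth)."""
    return simulate_bundle(small_config)
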