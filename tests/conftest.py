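import numpy as np
import pytest

from retsplice.simulate import SimConfig, generate_genome, spawn_variants


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=101, n_genes=8, n_chroms=2, chrom_len=50_000)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_transcripts(small_cfg, small_genome):
    txs = []
    for g in small_genome.genes:
        txs.extend(spawn_variants(g, small_cfg.variant_spec, seed=small_cfg.seed))
    return txs


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
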