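import numpy as np
import pandas as pd
import pytest

from hypoxiascreen import GrowthConfig, QpcrConfig, SimConfig, demo_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def demo_cfg():
    """The benchmark screen: 1,000 genes, 20 planted hits, fixed seed."""
    return demo_config(seed=11)


@pytest.fixture(scope="session")
def demo_screen(demo_cfg):
    from hypoxiascreen import simulate_screen

    return simulate_screen(demo_cfg)


@pytest.fixture
def noise_free_growth():
    return GrowthConfig(replicate_cv=0.0)


@pytest.fixture
def noise_free_qpcr():
    return QpcrConfig(noise_sd=0.0)


def random_abundance_table(rng, max_genes=20, max_probes=8):
    """A small random abundance table for oracle comparisons."""
    n_genes = rng.integers(1, max_genes + 1)
    rows = []
    k = 0
    for g in range(n_genes):
        for _ in range(rng.integers(1, max_probes + 1)):
            rows.append(
                (f"p{k}", f"g{g}",
                 float(rng.lognormal(0.0, 1.5)), float(rng.lognormal(0.0, 1.5)))
            )
            k += 1
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "signal_normoxia", "signal_hypoxia"]
    )
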