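import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orthodelta.simulate import SimConfig, generate_counts, generate_orthology

settings.register_profile("repro", derandomize=True, deadline=None, database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced-size generator configuration for fast unit tests."""
    return SimConfig(n_ogs=300, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    table, truth = generate_orthology(small_config)
    counts, meta = generate_counts(table, truth, small_config)
    return {"table": table, "truth": truth, "counts": counts, "meta": meta}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def nb_matrix(rng, n_genes, n_samples, dispersion=0.1, meanlog=4.0, sdlog=1.5):
    """A null NB count matrix with lognormal baseline abundances."""
    mean = rng.lognormal(meanlog, sdlog, n_genes)
    if dispersion <= 0:
        y = rng.poisson(np.tile(mean[:, None], (1, n_samples)))
    else:
        r = 1.0 / dispersion
        y = rng.negative_binomial(r, r / (r + mean[:, None]), size=(n_genes, n_samples))
    return pd.DataFrame(
        y,
        index=[f"OG{i:05d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
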