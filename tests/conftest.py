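"""Shared fixtures. Heavy simulated worlds are session-scoped."""

import numpy as np
import pytest

from phenosim.cohorts import PoolSpec, build_cc_pool
from phenosim.genosim import build_haplotype_pool, build_marker_map
from phenosim.pipeline import BenchmarkConfig, build_experiment


@pytest.fixture(scope="session")
def epi_exp():
    """The purely epistatic study arm: 401-marker chromosome, main penetrance
    table (target OR 4) and the five alternative-determinant tables."""
    return build_experiment("EPI", BenchmarkConfig(seed=101))


@pytest.fixture(scope="session")
def me_exp():
    """The main-effect study arm: 1,362-marker chromosome, mixed logistic
    model (per-allele OR 2.2255 at RL0-855) and five single-SNP alternatives."""
    return build_experiment("ME", BenchmarkConfig(seed=202))


@pytest.fixture(scope="session")
def epi_cc_small(epi_exp):
    """A 5-replicate (2,000-individual) pooled EPI case-control dataset."""
    return build_cc_pool(epi_exp.pool, epi_exp.main_model, PoolSpec(n_replicates=5, seed=55))


@pytest.fixture(scope="session")
def toy_markers():
    return build_marker_map(50, seed=7)


@pytest.fixture(scope="session")
def toy_pool(toy_markers):
    return build_haplotype_pool(toy_markers, ld_decay=0.8, pool_size=600, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
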