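import itertools

import numpy as np
import pytest

from multidcox.data_model import (
    ExpressionMatrix,
    FactorTable,
    build_strata,
    enumerate_pairs,
)
from multidcox.pair_statistics import build_design
from multidcox.simulation import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def planted_sim():
    """Small planted dataset: 600 genes, 12 strata x 5 samples, sigma 0.2."""
    cfg = SimulationConfig(n_genes=600, samples_per_stratum=5, sigma=0.2, rng_seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_design(planted_sim):
    _, factors, _ = planted_sim
    strata = build_strata(factors)
    pairs = enumerate_pairs(strata)
    return build_design(factors, pairs)


@pytest.fixture(scope="session")
def random_dataset():
    """Random Gaussian expression with a 3-factor balanced design (no signal)."""
    rng = np.random.default_rng(202)
    levels = list(itertools.product((-1, 1), (-1, 1), (-1, 0, 1)))
    rows = np.array([v for v in levels for _ in range(4)])
    sample_ids = [f"S{i}" for i in range(rows.shape[0])]
    factors = FactorTable(sample_ids, ["B1", "B2", "B3"], rows)
    expr = ExpressionMatrix(
        rng.normal(size=(80, rows.shape[0])),
        [f"g{i}" for i in range(80)],
        sample_ids,
    )
    return expr, factors


@pytest.fixture(scope="session")
def random_design(random_dataset):
    _, factors = random_dataset
    return build_design(factors, enumerate_pairs(build_strata(factors)))
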