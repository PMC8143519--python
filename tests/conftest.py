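import numpy as np
import pandas as pd
import pytest

from clustershift import normalize, tmm_factors
from clustershift.simulate import SimulationConfig, simulate_counts


def one_tissue_config(**kwargs) -> SimulationConfig:
    """Single-arm (soft tissue) config for speed; defaults otherwise."""
    kwargs.setdefault("tissues", ("soft_tissue",))
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """300-gene soft-tissue dataset with planted structure (seed 7)."""
    cfg = one_tissue_config(n_genes=300, seed=7)
    cm, st, gt = simulate_counts(cfg)
    return cfg, cm, st, gt


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    _, cm, st, _ = small_dataset
    expr = normalize(cm, tmm_factors(cm))
    return expr, st


@pytest.fixture()
def tiny_counts():
    """Hand-sized count matrix with lengths for TPM arithmetic."""
    from clustershift.expression import CountMatrix
    counts = pd.DataFrame(
        {"s1": [10, 40], "s2": [5, 5]},
        index=["gA", "gB"],
    )
    lengths = pd.Series([1000.0, 2000.0], index=["gA", "gB"])
    return CountMatrix(counts, lengths)
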