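import numpy as np
import pandas as pd
import pytest

import diffnet as dn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_table(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    features = features or [f"F{i + 1}" for i in range(m)]
    samples = samples or [f"S{j + 1}" for j in range(n)]
    return pd.DataFrame(values, index=features, columns=samples)


def make_condition(n_control, n_case, samples=None):
    labels = ["control"] * n_control + ["case"] * n_case
    if samples is None:
        samples = [f"S{j + 1}" for j in range(len(labels))]
    return pd.Series(labels, index=samples)


@pytest.fixture
def small_exp():
    """Deterministic 8-feature chain experiment, 40 samples per condition."""
    exp, _ = dn.simulate_experiment(
        m=8, n_control=40, n_case=40, graph="chain", edge_weight=0.45, seed=11
    )
    return exp


@pytest.fixture
def chain_truth():
    exp, truth = dn.simulate_experiment(
        m=10, n_control=150, n_case=150, graph="chain", edge_weight=0.45, seed=5
    )
    return exp, truth
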