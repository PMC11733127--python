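import warnings

import numpy as np
import pandas as pd
import pytest

import culturomix as cx


@pytest.fixture
def toy_tree():
    """((A:1,B:2):3,C:4); — total branch length 10."""
    return cx.tables_io.parse_newick("((A:1,B:2):3,C:4);")


@pytest.fixture
def toy_fraction_table():
    data = pd.DataFrame(
        [[0.2, 0.3, 0.5], [0.0, 0.4, 0.6], [1.0, 0.0, 0.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )
    return cx.AbundanceTable(data, mode="fraction")


@pytest.fixture(scope="session")
def small_experiment():
    """One small simulated campaign shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cx.simulate_experiment(
            seed=11, n_taxa=40, n_donors=3, n_modifications=8, depth=5000
        )


@pytest.fixture(scope="session")
def small_fractions(small_experiment):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cx.close_composition(small_experiment.counts)


def random_fraction_table(rng, n_samples, n_features, prefix="s"):
    values = rng.random((n_samples, n_features))
    values /= values.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(n_samples)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    return cx.AbundanceTable(frame, mode="fraction")
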