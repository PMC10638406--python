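import numpy as np
import pandas as pd
import pytest

from ppnet import EdgeSet, FeatureMatrix, IndividualNetwork, LabelVector, SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """6 samples x 5 features with non-trivial values."""
    vals = rng.normal(size=(6, 5))
    return FeatureMatrix(
        pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(6)],
            columns=[f"g{j}" for j in range(5)],
        ),
        modality="rna",
    )


@pytest.fixture
def small_edges():
    return EdgeSet([("g0", "g1"), ("g0", "g2"), ("g2", "g3"), ("g1", "g4")])


def make_networks(rng, edge_set, n=5, prefix="s"):
    return [
        IndividualNetwork(f"{prefix}{k}", edge_set, rng.uniform(0, 1, len(edge_set)), scaled=True)
        for k in range(n)
    ]


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-modality dataset with both node and edge signal."""
    spec = SimulationSpec(
        n_train=30, n_test=15, p_a=12, p_b=12, block_size=6, n_shift=6,
        mean_shift=2.0, block_rho=(0.8, 0.0), seed=7,
    )
    train, test, y_tr, y_te = simulate_dataset(spec)
    return {"train": train, "test": test, "labels_train": y_tr, "labels_test": y_te}


@pytest.fixture
def labels6():
    return LabelVector(
        pd.Series(
            ["case", "case", "case", "control", "control", "control"],
            index=[f"s{i}" for i in range(6)],
        )
    )
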