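import numpy as np
import pytest

from dcgn import DCGNConfig, ExpressionDataset, SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 balanced classes x 40 samples, 256 genes, strong signal."""
    return simulate_dataset(
        SimulationSpec(
            n_classes=3,
            class_counts=(40, 40, 40),
            n_genes=256,
            n_informative=24,
            effect_size=3.0,
            seed=7,
        )
    )


@pytest.fixture
def imbalanced_dataset():
    """2-class dataset with a 100:10 imbalance for SMOTE tests."""
    return simulate_dataset(
        SimulationSpec(
            n_classes=2,
            class_counts=(100, 10),
            n_genes=20,
            n_informative=4,
            effect_size=2.0,
            seed=11,
        )
    )


@pytest.fixture
def small_config():
    """Network scaled down for fast tests; architecture otherwise default."""
    return DCGNConfig(
        fc_nodes=16,
        conv1_kernels=4,
        conv2_kernels=3,
        gru_units=3,
        classifier_nodes=(8, 6, 5),
        n_classes=3,
        dropout_rates=(0.0, 0.0),
        batch_size=16,
        epochs=3,
        seed=3,
    )


def make_dataset(values, labels, label_names=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        values=values,
        labels=np.asarray(labels, dtype=int),
        label_names=label_names,
    )
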