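import numpy as np
import pytest

import otulearn as ol


@pytest.fixture(scope="session")
def small_dataset():
    """Modest synthetic community with a planted 8-taxon signal."""
    spec = ol.SyntheticSpec(
        n_groups=40, n_taxa=60, n_signal_taxa=8, noise_sd=0.1, seed=11
    )
    return ol.generate(spec)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    table, target, truth = small_dataset
    (tr, tr_y), (te, te_y) = ol.group_split(table, target, 0.165, seed=5)
    (tr_s, te_s), stats = ol.standardize(tr, [te])
    return {
        "train_raw": tr, "train_y": tr_y, "test_raw": te, "test_y": te_y,
        "train": tr_s, "test": te_s, "stats": stats, "truth": truth,
    }


@pytest.fixture(scope="session")
def trained_nn(small_split):
    return ol.train_nn(
        small_split["train"].counts,
        small_split["train_y"].values,
        ol.NNTrainConfig(seed=3),
        groups=small_split["train"].group_ids,
    )


@pytest.fixture(scope="session")
def trained_rf(small_split):
    return ol.train_rf(
        small_split["train"].counts,
        small_split["train_y"].values,
        ol.ForestConfig(n_trees=100, seed=3),
    )


@pytest.fixture
def tiny_table():
    """5 samples x 4 taxa with groups, hand-sized for exact checks."""
    counts = np.array(
        [[5, 0, 3, 2], [4, 1, 3, 2], [0, 9, 1, 0], [2, 2, 2, 4], [1, 0, 0, 9]]
    )
    return ol.OtuTable(
        sample_ids=[f"s{i}" for i in range(5)],
        taxon_ids=["tA", "tB", "tC", "tD"],
        counts=counts,
        group_ids=["g1", "g1", "g2", "g2", "g3"],
    )
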