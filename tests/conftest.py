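import numpy as np
import pytest

from specsel import (
    FitnessSpec,
    KernelSpec,
    SvmParams,
    from_arrays,
    generate_dataset,
    high_concentration_config,
    random_parameter_search,
    split_by_role,
)


@pytest.fixture(scope="session")
def high_fixture():
    """Default five-class synthetic dataset (seed 1) split by role."""
    cfg = high_concentration_config(seed=1)
    dataset, planted = generate_dataset(cfg)
    train, test, commercial = split_by_role(dataset)
    return {
        "config": cfg,
        "dataset": dataset,
        "planted": planted,
        "train": train,
        "test": test,
        "commercial": commercial,
    }


@pytest.fixture(scope="session")
def searched_params(high_fixture):
    """Top-ranked SVM parameters from a 20-combination random search on the
    training partition of the session fixture."""
    ranked = random_parameter_search(
        high_fixture["train"], n_combinations=20, rng_seed=1
    )
    return ranked[0][0]


@pytest.fixture(scope="session")
def reference_params():
    """Hand-set gaussian parameters in the magnitude range of the reference
    configuration (large C, tight tolerance, width 5)."""
    return SvmParams(C=10_000.0, epsilon=1e-6, kernel=KernelSpec("gaussian", sigma=5.0))


def make_blobs_2d(seed=0, n_per=20, separation=6.0, noise=1.0):
    """Two well-separated 2-D clusters labeled +1 / -1."""
    rng = np.random.default_rng(seed)
    pos = rng.normal([separation / 2, 0.0], noise, size=(n_per, 2))
    neg = rng.normal([-separation / 2, 0.0], noise, size=(n_per, 2))
    X = np.vstack([pos, neg])
    labels = ["+1"] * n_per + ["-1"] * n_per
    return from_arrays(X, labels, ["train"] * 2 * n_per, class_levels=["+1", "-1"])


def make_multiclass_2d(seed=0, n_classes=3, n_per=10, separation=8.0, noise=1.0):
    """Small multiclass 2-D set: class centers on a circle."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k in range(n_classes):
        theta = 2 * np.pi * k / n_classes
        center = separation * np.array([np.cos(theta), np.sin(theta)])
        rows.append(rng.normal(center, noise, size=(n_per, 2)))
        labels.extend([f"c{k}"] * n_per)
    X = np.vstack(rows)
    return from_arrays(
        X, labels, ["train"] * len(labels),
        class_levels=[f"c{k}" for k in range(n_classes)],
    )


@pytest.fixture
def separable_binary():
    return make_blobs_2d(seed=3, separation=8.0, noise=0.8)


@pytest.fixture
def separable_multiclass():
    return make_multiclass_2d(seed=5, n_classes=3, separation=10.0, noise=0.8)
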