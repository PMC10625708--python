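import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellstate import (
    ExpressionMatrix,
    LabeledDataset,
    Layer,
    SyntheticSpec,
    generate,
    normalize_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(values, labels, layer=Layer.LOG2P1, class_names=None):
    """Small labeled dataset with auto-generated cell/gene IDs."""
    values = np.asarray(values, dtype=float)
    cells = tuple(f"cell{i}" for i in range(values.shape[0]))
    genes = tuple(f"g{j}" for j in range(values.shape[1]))
    if class_names is None:
        class_names = tuple(sorted(set(labels)))
    return LabeledDataset(ExpressionMatrix(cells, genes, values, layer), tuple(labels), class_names)


@pytest.fixture(scope="session")
def small_sim():
    """A modest 3-class simulated dataset (raw + normalized), with ground truth."""
    spec = SyntheticSpec(
        class_sizes=(40, 60, 50),
        class_names=("alpha", "beta", "gamma"),
        n_genes=80,
        n_markers_per_class=5,
        marker_fold_change=16.0,
        seed=11,
    )
    raw, truth = generate(spec)
    return raw, normalize_dataset(raw), truth


@pytest.fixture(scope="session")
def strong_sim():
    """A larger, strongly separable dataset for learner-level tests."""
    spec = SyntheticSpec(
        class_sizes=(60, 120, 90),
        class_names=("alpha", "beta", "gamma"),
        n_genes=200,
        n_markers_per_class=8,
        marker_fold_change=16.0,
        seed=7,
    )
    raw, truth = generate(spec)
    return normalize_dataset(raw), truth
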