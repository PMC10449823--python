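import numpy as np
import pytest

from herdid import (
    CaptureConfig,
    ClassifierSpec,
    SplitPlan,
    generate_study,
    prepare_experiment,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """5 individuals, small budgets — cheap shared fixture for engine tests."""
    config = CaptureConfig(n_individuals=5, master_seed=11)
    plan = SplitPlan(
        train_per_individual=2, val_total=20, test_total=20, n_unlabeled=60
    )
    return generate_study(config, plan)


@pytest.fixture(scope="session")
def tiny_data(tiny_dataset):
    return prepare_experiment(tiny_dataset)


@pytest.fixture(scope="session")
def reference_spec(tiny_data):
    return ClassifierSpec(
        backbone="nearest-centroid-reference", n_classes=tiny_data.n_classes
    )


@pytest.fixture(scope="session")
def separable_images():
    """Two classes separated by which half of the image carries the pattern.

    A reference linear classifier attains accuracy 1.0 on this
    construction, so any competent trained model must approach it.
    """
    rng = np.random.default_rng(42)
    images, labels = [], []
    for label in (0, 1):
        for _ in range(50):
            img = rng.uniform(0.0, 0.25, size=(16, 32))
            cols = slice(2, 14) if label == 0 else slice(18, 30)
            img[4:12, cols] += 0.65
            images.append(np.clip(img, 0, 1))
            labels.append(label)
    return np.array(images, dtype=np.float32), np.array(labels)
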