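import numpy as np
import pytest

from masscontext.augmentation import AugmentationPlan
from masscontext.datatypes import Density, Label
from masscontext.estimator import ContextEnsembleClassifier
from masscontext.synthetic import SyntheticConfig, generate_dataset, generate_region


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_region():
    r = np.random.default_rng(7)
    return generate_region(Label.BENIGN, Density.II, r, region_id="fix_benign")


@pytest.fixture(scope="session")
def malignant_region():
    r = np.random.default_rng(8)
    return generate_region(Label.MALIGNANT, Density.III, r, region_id="fix_malig")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial phantom dataset shared across tests."""
    return generate_dataset(SyntheticConfig(n_per_class=12, seed=3))


def desk_scale_plan(seed: int = 42) -> AugmentationPlan:
    """Reduced augmentation used for CPU-scale training runs."""
    return AugmentationPlan(
        stride=20, angles=(0, 180), flip=True, scale_percents=(5, 10), seed=seed
    )


@pytest.fixture(scope="session")
def end_to_end_run():
    """Full pipeline at study scale: 200 phantoms, MC2 extraction, the
    reduced-depth backbone and RBF-SVM stacking, fixed seed.

    Shared session-wide because fitting takes minutes on one CPU.
    """
    ds = generate_dataset(SyntheticConfig(n_per_class=100, seed=42))
    clf = ContextEnsembleClassifier(
        scheme="MC2",
        variant="tiny",
        fusion="stack-rbf",
        augmentation_plan=desk_scale_plan(),
        epochs=8,
        random_state=42,
    )
    clf.fit(ds.train)

    y_test = np.array([int(r.label) for r in ds.test])
    roi_probs = clf.roi_probabilities(ds.test)
    stacked_acc = float((clf.predict(ds.test) == y_test).mean())
    # accuracy of the backbone on the first (whole-crop) ROI alone
    single_acc = float(((roi_probs[:, 0, 1] >= 0.5).astype(int) == y_test).mean())
    return {
        "dataset": ds,
        "clf": clf,
        "y_test": y_test,
        "roi_probs": roi_probs,
        "stacked_accuracy": stacked_acc,
        "single_roi_accuracy": single_acc,
    }
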