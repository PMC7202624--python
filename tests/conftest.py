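import numpy as np
import pytest

from alveoquant import phantom, segmentation
from alveoquant.postprocess import SegmentationMask


def make_mask(arr, spacing_um=1.0, fov=None):
    arr = np.asarray(arr, dtype=bool)
    if fov is None:
        fov = np.ones(arr.shape, dtype=bool)
    return SegmentationMask(mask=arr, spacing_um=spacing_um, fov_mask=fov)


@pytest.fixture
def mask_factory():
    return make_mask


@pytest.fixture(scope="session")
def small_bank():
    """Reduced feature bank for fast training in unit/CLI tests."""
    return segmentation.FeatureBankConfig(scales=(1.0, 2.0, 4.0))


def train_phantom_model(
    n_train: int,
    size: int = 160,
    snr: float = 4.0,
    bank: segmentation.FeatureBankConfig = segmentation.FeatureBankConfig(),
    n_trees: int = 100,
    seed0: int = 100,
    label_fraction: float = 0.04,
    do_cfs: bool = True,
):
    """Train a classifier on a family of phantoms; returns (model, specs)."""
    sets = []
    specs = []
    for k in range(n_train):
        spec = phantom.PhantomSpec(
            image_size_px=size,
            n_seeds=14 + (k % 8),
            width_um_mean=9.0 + (k % 3),
            width_um_sd=2.0,
            edge_keep_prob=0.85,
            snr=snr,
            seed=seed0 + k,
        )
        specs.append(spec)
        image, truth = phantom.generate_phantom(spec)
        stack = segmentation.compute_features(image, bank=bank)
        labels = phantom.make_training_labels(truth, fraction=label_fraction, seed=seed0 + k)
        sets.append(
            segmentation.collect_instances(stack, labels, source_id=image.source_id)
        )
    ts = segmentation.concat_training_sets(sets)
    ts = segmentation.undersample(ts, seed=0)
    selected = segmentation.select_features_cfs(ts) if do_cfs else None
    model = segmentation.train_forest(
        ts, n_trees=n_trees, seed=0, selected_features=selected, bank=bank
    )
    return model, specs


@pytest.fixture(scope="session")
def phantom_model(small_bank):
    """Classifier trained on a small phantom family (reduced bank, fast)."""
    model, specs = train_phantom_model(
        n_train=3, size=128, snr=6.0, bank=small_bank, n_trees=60
    )
    return model
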