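"""Shared fixtures: small synthetic recordings and separable image sets."""

import numpy as np
import pytest

from neurofuse.images import ImageDataset
from neurofuse.simulate import SimConfig, simulate_trialset


@pytest.fixture(scope="session")
def small_trialset():
    """30 trials (10 per class) with the default class-effect matrices."""
    return simulate_trialset(SimConfig(trials_per_class=10, seed=7))


@pytest.fixture(scope="session")
def null_trialset():
    """No class information: zero ERD depth, zero EMG gain."""
    cfg = SimConfig(trials_per_class=10, seed=11,
                    erd_depth=np.zeros((3, 9)), emg_gain=np.zeros((3, 4)))
    return simulate_trialset(cfg)


def make_separable_images(n_per_class=10, width=403, seed=0, noise=0.1,
                          test_fraction=1 / 3, permute_labels=False):
    """Three classes, each marked by a bright band of columns, plus noise."""
    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for k in range(3):
        for _ in range(n_per_class):
            img = 0.5 + noise * rng.standard_normal((46, width))
            img[:, k * 40:(k + 1) * 40] += 0.4
            imgs.append(np.clip(img, 0, 1))
            labels.append(k)
    imgs = np.asarray(imgs)
    labels = np.asarray(labels)
    if permute_labels:
        labels = rng.permutation(labels)
    split = np.array(["train"] * len(imgs))
    n_test = int(round(test_fraction * len(imgs)))
    if n_test:
        split[rng.choice(len(imgs), size=n_test, replace=False)] = "test"
    return ImageDataset(images=imgs, labels=labels, split=split,
                        provenance=[np.arange(5)] * len(imgs),
                        layout=[], layout_mode="fused")


@pytest.fixture
def separable_images():
    return make_separable_images()
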