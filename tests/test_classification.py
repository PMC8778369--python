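"""The CNN classifier operations and the transfer-learning contract."""

import numpy as np
import pytest

from neurofuse.classification import (
    CNNClassifier,
    NetSpec,
    TrainConfig,
    build_network,
    grid_search_lr,
    predict,
    train,
    transfer_learn,
)
from tests.conftest import make_separable_images

SMALL = NetSpec.small(403)


def bundles_equal(a, b):
    return all(np.array_equal(pa[k], pb[k])
               for pa, pb in zip(a.parameters, b.parameters) for k in pa)


class TestBuild:
    def test_same_seed_identical_parameters(self):
        assert bundles_equal(build_network(SMALL, 5), build_network(SMALL, 5))

    def test_forward_probabilities_normalised(self):
        b = build_network(SMALL, 0)
        x = np.random.default_rng(0).random((3, 46, 403))
        _, probs = predict(b, x)
        assert probs.shape == (3, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_images_share_bias_response(self):
        b = build_network(SMALL, 1)
        _, p = predict(b, np.zeros((2, 46, 403)))
        assert np.array_equal(p[0], p[1])

    def test_five_blocks_enforced(self):
        with pytest.raises(ValueError, match="5 convolutional blocks"):
            NetSpec(input_shape=(46, 403, 1), conv_filters=(8, 16, 32))


class TestTrain:
    def test_separable_fixture_reaches_high_train_accuracy(self):
        ds = make_separable_images(n_per_class=10)
        fitted = train(build_network(SMALL, 0), ds, TrainConfig(seed=0))
        X, y = ds.subset("train")
        pred, _ = predict(fitted, X)
        assert (pred == y).mean() >= 0.9

    def test_zero_learning_rate_is_a_null_step(self, separable_images):
        b = build_network(SMALL, 3)
        f = train(b, separable_images, TrainConfig(learning_rate=0.0, seed=0))
        assert bundles_equal(b, f)

    def test_input_bundle_untouched(self, separable_images):
        b = build_network(SMALL, 2)
        snapshot = [{k: v.copy() for k, v in p.items()} for p in b.parameters]
        train(b, separable_images, TrainConfig(seed=0, max_epochs=1))
        assert all(np.array_equal(p[k], s[k])
                   for p, s in zip(b.parameters, snapshot) for k in p)

    def test_history_is_monotone_and_validated_every_third_iteration(self):
        ds = make_separable_images(n_per_class=12)
        split = ds.split.copy()
        split[np.where(split == "train")[0][:6]] = "val"
        ds.split = split
        cfg = TrainConfig(seed=0, max_epochs=2, validation_frequency=3)
        f = train(build_network(SMALL, 0), ds, cfg)
        its = f.history["iteration"]
        assert all(b > a for a, b in zip(its, its[1:]))
        assert f.history["val_iteration"]
        assert all(v % 3 == 0 for v in f.history["val_iteration"])

    def test_empty_training_split_errors(self, separable_images):
        ds = separable_images
        ds.split = np.array(["test"] * len(ds.images))
        with pytest.raises(ValueError, match="empty"):
            train(build_network(SMALL, 0), ds, TrainConfig())

    def test_nan_images_rejected(self, separable_images):
        separable_images.images[:, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(build_network(SMALL, 0), separable_images, TrainConfig())


class TestGridSearch:
    def test_single_point_grid_returns_it(self, separable_images):
        cfg = TrainConfig(max_epochs=1, lr_grid=(0.02,))
        assert grid_search_lr(separable_images, cfg, spec=SMALL) == 0.02

    def test_tie_breaks_to_smaller_rate(self):
        # all-identical images carry no information: every rate scores the
        # same validation accuracy, so the tie rule must pick the smallest
        ds = make_separable_images(n_per_class=4, noise=0.0)
        ds.images[:] = 0.5
        cfg = TrainConfig(max_epochs=1, lr_grid=(0.5, 0.05))
        assert grid_search_lr(ds, cfg, spec=SMALL, seed=0) == 0.05

    def test_returned_rate_maximises_validation_accuracy(self):
        ds = make_separable_images(n_per_class=8, seed=4)
        split = ds.split.copy()
        split[np.where(split == "train")[0][:6]] = "val"
        ds.split = split
        cfg = TrainConfig(max_epochs=3, lr_grid=(0.1, 0.01, 0.001))
        best = grid_search_lr(ds, cfg, spec=SMALL, seed=1)
        accs = {}
        for lr in cfg.lr_grid:
            f = train(build_network(SMALL, 1), ds, cfg.replace(learning_rate=lr))
            X, y = ds.subset("val")
            accs[lr] = (predict(f, X)[0] == y).mean()
        assert accs[best] == max(accs.values())

    def test_empty_grid_rejected(self, separable_images):
        with pytest.raises(ValueError, match="empty"):
            grid_search_lr(separable_images, TrainConfig(lr_grid=()))


class TestTransferLearning:
    @pytest.fixture(scope="class")
    def pretrained(self):
        ds = make_separable_images(n_per_class=8, seed=0)
        return train(build_network(SMALL, 0), ds,
                     TrainConfig(seed=0, max_epochs=3))

    def test_requires_multimodal_provenance(self, pretrained, separable_images):
        single = pretrained.copy()
        single.provenance = "single_modal"
        with pytest.raises(ValueError, match="provenance"):
            transfer_learn(single, separable_images)

    def test_shape_mismatch_rejected(self, pretrained):
        narrow = make_separable_images(n_per_class=4, width=279, seed=1)
        with pytest.raises(ValueError, match="width"):
            transfer_learn(pretrained, narrow)

    def test_zero_epochs_returns_pretrained_parameters(self, pretrained):
        ds = make_separable_images(n_per_class=4, seed=2)
        tl = transfer_learn(pretrained, ds,
                            TrainConfig(learning_rate=3e-4, max_epochs=0))
        assert bundles_equal(pretrained, tl)

    def test_frozen_base_is_bit_identical(self, pretrained):
        ds = make_separable_images(n_per_class=6, seed=3)
        tl = transfer_learn(pretrained, ds,
                            TrainConfig(learning_rate=3e-4, seed=1))
        for i in range(4):
            for k in pretrained.parameters[i]:
                assert np.array_equal(pretrained.parameters[i][k],
                                      tl.parameters[i][k])
        assert not np.array_equal(pretrained.parameters[4]["W"],
                                  tl.parameters[4]["W"])
        assert tl.provenance == "transfer_learned"

    def test_strict_mode_freezes_all_conv(self, pretrained):
        ds = make_separable_images(n_per_class=6, seed=3)
        tl = transfer_learn(pretrained, ds,
                            TrainConfig(learning_rate=3e-4, seed=1),
                            freeze_all_conv=True)
        for i in range(5):
            for k in pretrained.parameters[i]:
                assert np.array_equal(pretrained.parameters[i][k],
                                      tl.parameters[i][k])


class TestPredict:
    def test_batch_equals_per_image(self, separable_images):
        b = build_network(SMALL, 0)
        X = separable_images.images[:5]
        batch_pred, batch_probs = predict(b, X)
        for i in range(5):
            p_i, pr_i = predict(b, X[i:i + 1])
            assert p_i[0] == batch_pred[i]
            assert np.allclose(pr_i[0], batch_probs[i], atol=1e-6)

    def test_nan_input_rejected(self):
        b = build_network(SMALL, 0)
        x = np.zeros((1, 46, 403))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            predict(b, x)

    def test_overfit_model_recalls_training_image(self):
        ds = make_separable_images(n_per_class=3, test_fraction=0.0)
        f = train(build_network(SMALL, 0), ds, TrainConfig(seed=0))
        X, y = ds.subset("train")
        pred, _ = predict(f, X[:3])
        assert (pred == y[:3]).all()


class TestModelObjects:
    def test_fit_returns_results_with_summary(self):
        ds = make_separable_images(n_per_class=6)
        res = CNNClassifier(ds, SMALL, seed=0).fit(TrainConfig(max_epochs=2))
        assert 0.0 <= res.accuracy("test") <= 100.0
        cm = res.confusion("test")
        assert cm.sum() == (ds.split == "test").sum()
        text = res.summary()
        assert "provenance" in text and "test accuracy" in text
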