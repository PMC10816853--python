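"""Model contract, loss registry wiring, and the training loop."""

import numpy as np
import pytest

from aspseg import LossConfig, TrainConfig, build_model, evaluate, preset, train
from aspseg.asp import LraspWeightNet, fit_grouping
from aspseg.exceptions import ConfigError, DataError
from aspseg.model import UNet
from aspseg.train import LOSS_NAMES, Adam, batch_loss, fit_grouping_for, kfold_split, make_loss


def _grouping_for(name, dataset):
    strategies = {"qr_asp": "quantile", "vr_asp": "value",
                  "cr_asp": "cluster", "sr_asp": "cluster"}
    if name not in strategies:
        return None
    return fit_grouping_for(dataset, strategies[name])


class TestModel:
    def test_forward_shape_and_range(self, rng):
        model = build_model("unet3-8", seed=0)
        out = model.predict(rng.random((2, 64, 64)).astype(np.float32))
        assert out.shape == (2, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_same_seed_identical_parameters(self):
        a, b = build_model("unet3-8", seed=5), build_model("unet3-8", seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_constant_zero_input_finite(self):
        model = build_model("unet3-8", seed=1)
        out = model.predict(np.zeros((1, 32, 32), dtype=np.float32))
        assert np.isfinite(out).all()

    def test_unknown_descriptor_rejected(self):
        with pytest.raises(ConfigError):
            build_model("resnet-152")

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model = build_model("unet3-8", seed=2)
        x = rng.random((1, 32, 32)).astype(np.float32)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        again = UNet.load(path)
        assert np.array_equal(model.predict(x), again.predict(x))


class TestLossRegistry:
    @pytest.mark.parametrize("name", LOSS_NAMES)
    def test_every_loss_trains_one_step_with_finite_gradients(self, name,
                                                              small_dataset):
        cfg = LossConfig()
        grouping = _grouping_for(name, small_dataset)
        net = (LraspWeightNet(image_size=(32, 32), seed=0)
               if name == "lr_asp" else None)
        loss_fn = make_loss(name, cfg, grouping, net)
        model = build_model("unet3-8", seed=3)
        batch = small_dataset[:2]
        preds = model.forward(np.stack([s.image for s in batch]).astype(np.float32))
        loss = batch_loss(preds, batch, loss_fn)
        assert np.isfinite(loss.item())
        opt = Adam(model.parameters + (net.parameters if net else []), lr=1e-4)
        opt.zero_grad()
        loss.backward()
        grads = [p.grad for p in model.parameters if p.grad is not None]
        assert grads, "no gradient reached the model"
        assert all(np.isfinite(g).all() for g in grads)
        opt.step()

    def test_unknown_loss_rejected(self):
        with pytest.raises(ConfigError):
            make_loss("tversky", LossConfig())

    def test_grouping_required_before_training(self, small_dataset):
        cfg = TrainConfig(loss_name="cr_asp", epochs=1, image_size=(32, 32))
        with pytest.raises(DataError):
            train(small_dataset, cfg)

    def test_strategy_mismatch_rejected(self, small_dataset):
        wrong = fit_grouping_for(small_dataset, "quantile")
        with pytest.raises(ConfigError):
            make_loss("cr_asp", LossConfig(), wrong)


class TestPerSampleWiring:
    def test_batch_loss_is_mean_of_per_sample_losses(self, small_dataset):
        grouping = fit_grouping_for(small_dataset, "cluster")
        loss_fn = make_loss("cr_asp", LossConfig(), grouping)
        model = build_model("unet3-8", seed=7)
        batch = small_dataset[:4]
        images = np.stack([s.image for s in batch]).astype(np.float32)
        preds = model.forward(images)
        combined = batch_loss(preds, batch, loss_fn).item()
        singles = []
        for s in batch:
            p = model.forward(s.image[None].astype(np.float32))
            singles.append(loss_fn(p[0, 0], s.mask, s.meta).item())
        assert combined == pytest.approx(np.mean(singles), abs=1e-6)

    def test_batch_loss_invariant_to_sample_permutation(self, small_dataset):
        grouping = fit_grouping_for(small_dataset, "cluster")
        loss_fn = make_loss("cr_asp", LossConfig(), grouping)
        model = build_model("unet3-8", seed=7)
        batch = small_dataset[:4]
        perm = [batch[i] for i in (2, 0, 3, 1)]

        def batch_val(bb):
            preds = model.forward(np.stack([s.image for s in bb]).astype(np.float32))
            return batch_loss(preds, bb, loss_fn).item()

        assert batch_val(batch) == pytest.approx(batch_val(perm), abs=1e-6)


class TestTraining:
    def test_loss_descends_on_small_run(self, small_dataset):
        cfg = TrainConfig(loss_name="hybrid", epochs=3, image_size=(32, 32),
                          seed=13, val_fraction=0.0)
        record, _ = train(small_dataset, cfg)
        assert record.train_losses[-1] < record.train_losses[0]

    def test_trained_model_beats_untrained(self, small_dataset):
        cfg = TrainConfig(loss_name="hybrid", epochs=30, image_size=(32, 32),
                          seed=13, val_fraction=0.0, model_descriptor="unet3-8")
        _, model = train(small_dataset, cfg)
        trained = evaluate(model, small_dataset).dsc
        untrained = evaluate(build_model("unet3-8", seed=13), small_dataset).dsc
        assert trained > untrained

    def test_record_serializes(self, small_dataset):
        cfg = TrainConfig(loss_name="bce", epochs=1, image_size=(32, 32),
                          val_fraction=0.25)
        record, _ = train(small_dataset, cfg)
        text = record.to_json()
        assert '"train_loss"' in text and '"val_dsc"' in text

    def test_evaluate_deterministic(self, small_dataset):
        model = build_model("unet3-8", seed=4)
        a = evaluate(model, small_dataset)
        b = evaluate(model, small_dataset)
        assert a.dsc == b.dsc and a.sensitivity == b.sensitivity

    def test_evaluate_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            evaluate(build_model("unet3-8"), [])


class TestKfold:
    def test_partitions_cover_everything_once(self):
        folds = kfold_split(23, k=5, seed=1)
        assert len(folds) == 5
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test.tolist()) == list(range(23))
        for tr, te in folds:
            assert set(tr) & set(te) == set()
            assert len(tr) + len(te) == 23

    def test_bad_k_rejected(self):
        with pytest.raises(DataError):
            kfold_split(5, k=1)
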