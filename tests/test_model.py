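"""U-Net architecture, training recipe, inference and triage."""

import numpy as np
import pytest

from phasestain.model import (ModelConfig, PredictionImage, TrainConfig, UNet,
                              build_unet, load_model, predict, prediction_mask,
                              save_model, train_model, triage_fov)
from phasestain.prep import DatasetSplit, SamplePair, split_dataset
from phasestain.qpi import OpticalConfig, PlaneStack


def toy_pairs(rng, n=12, field=32, thresh=0.6):
    """Tiny synthetic mapping: label = smooth blob where input is high."""
    from scipy.ndimage import gaussian_filter
    pairs = []
    for i in range(n):
        base = gaussian_filter(rng.random((field, field)), 4.0)
        x = (base - base.min()) / np.ptp(base)
        label = np.clip((x - thresh) / (1 - thresh), 0, 1)
        stack = PlaneStack(x[None].astype(np.float32),
                           OpticalConfig(n_planes=1))
        pairs.append(SamplePair(stack, label, acquisition_id=f"p{i:03d}"))
    return pairs


TOY_MODEL = ModelConfig(in_planes=1, base_features=8, depth=2, seed=0)


class TestArchitecture:
    def test_output_shape_matches_input_352(self):
        net, _ = build_unet(ModelConfig(in_planes=1, base_features=16, depth=4))
        out = net.forward(np.zeros((1, 1, 352, 352), dtype=np.float32))
        assert out.shape == (1, 1, 352, 352)

    def test_feature_reduction_cuts_parameters_15x(self):
        _, n64 = build_unet(ModelConfig(in_planes=1, base_features=64, depth=4))
        _, n16 = build_unet(ModelConfig(in_planes=1, base_features=16, depth=4))
        assert n64 // n16 == 15

    def test_parameter_count_matches_hand_count(self):
        """Layer-by-layer count for depth 2, base 8, 1 in/out channel.

        enc: (9*1*8+8)+(9*64+8) + (9*128+16)+(9*256+16)
        bottleneck: (9*512+32)+(9*1024+32)
        up2: (4*1024+16)+(9*512+16)+(9*256+16)
        up1: (4*128+8)+(9*128+8)+(9*64+8); final 1x1: 8+1
        """
        _, n = build_unet(ModelConfig(in_planes=1, base_features=8, depth=2))
        assert n == 29321

    def test_indivisible_input_rejected(self):
        net, _ = build_unet(TOY_MODEL)
        with pytest.raises(ValueError, match="pad"):
            net.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(base_features=24)
        with pytest.raises(ValueError):
            ModelConfig(in_planes=3)


class TestTraining:
    def test_overfits_copies_of_one_pair(self, rng):
        """50 copies of a single pair drive the training MSE below 1e-3."""
        one = toy_pairs(rng, n=1)[0]
        pairs = [SamplePair(one.input_stack, one.label_image,
                            acquisition_id=f"c{i:03d}") for i in range(50)]
        split = split_dataset([p.acquisition_id for p in pairs], seed=0)
        model, hist = train_model(pairs, split, TOY_MODEL,
                                  TrainConfig(max_epochs=30, batch_size=4,
                                              early_stop_patience=30, seed=0))
        assert hist.train_loss[-1] < 1e-3

    def test_checkpoint_returns_best_validation_weights(self, rng):
        pairs = toy_pairs(rng, n=14)
        split = split_dataset([p.acquisition_id for p in pairs], seed=1)
        model, hist = train_model(pairs, split, TOY_MODEL,
                                  TrainConfig(max_epochs=6, batch_size=4,
                                              early_stop_patience=6, seed=0))
        from phasestain.model import evaluate_loss, _pairs_to_arrays
        by_id = {p.acquisition_id: p for p in pairs}
        xv, yv = _pairs_to_arrays([by_id[i] for i in split.val_ids], "regression")
        assert evaluate_loss(model, xv, yv) == pytest.approx(hist.best_val_loss,
                                                             rel=1e-6)

    def test_early_stopping_on_plateau(self, rng):
        """With a vanishing learning rate the val loss never improves,
        so training stops after exactly `patience` stale epochs."""
        pairs = toy_pairs(rng, n=12)
        split = split_dataset([p.acquisition_id for p in pairs], seed=0)
        _, hist = train_model(pairs, split, TOY_MODEL,
                              TrainConfig(max_epochs=20, batch_size=4,
                                          learning_rate=1e-15,
                                          early_stop_patience=3, seed=0))
        assert hist.stopped_early
        assert len(hist.val_loss) == 1 + 3

    def test_pair_order_permutation_stable(self, rng):
        """Reordering the training pairs moves the best val loss < 10%."""
        pairs = toy_pairs(rng, n=16)
        split = split_dataset([p.acquisition_id for p in pairs], seed=2)
        perm = DatasetSplit(split.test_ids, split.val_ids,
                            tuple(reversed(split.train_ids)), seed=split.seed)
        tcfg = TrainConfig(max_epochs=8, batch_size=4, early_stop_patience=8,
                           seed=0)
        _, h1 = train_model(pairs, split, TOY_MODEL, tcfg)
        _, h2 = train_model(pairs, perm, TOY_MODEL, tcfg)
        assert h2.best_val_loss == pytest.approx(h1.best_val_loss, rel=0.10)

    def test_empty_sets_rejected(self, rng):
        pairs = toy_pairs(rng, n=12)
        split = DatasetSplit(tuple(p.acquisition_id for p in pairs), (), ())
        with pytest.raises(ValueError, match="non-empty"):
            train_model(pairs, split, TOY_MODEL, TrainConfig())


class TestPredict:
    def test_inference_deterministic(self, rng):
        net, _ = build_unet(TOY_MODEL)
        stack = PlaneStack(rng.random((1, 32, 32)).astype(np.float32),
                           OpticalConfig(n_planes=1))
        a, b = predict(net, stack), predict(net, stack)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.model_fingerprint == b.model_fingerprint

    def test_plane_count_mismatch_names_expected(self, rng):
        net, _ = build_unet(ModelConfig(in_planes=4, base_features=8, depth=2))
        stack = PlaneStack(rng.random((2, 32, 32)), OpticalConfig(n_planes=2))
        with pytest.raises(ValueError, match="4 input planes"):
            predict(net, stack)

    def test_output_in_unit_interval(self, rng):
        net, _ = build_unet(TOY_MODEL)
        stack = PlaneStack(rng.random((1, 64, 64)).astype(np.float32),
                           OpticalConfig(n_planes=1))
        pred = predict(net, stack)
        assert pred.values.min() >= 0 and pred.values.max() <= 1

    def test_prediction_mask_fixed_cut(self):
        pred = PredictionImage(np.linspace(0, 1, 64).reshape(8, 8))
        mask = prediction_mask(pred, method="fixed", level=0.5)
        np.testing.assert_array_equal(mask, pred.values > 0.5)

    def test_prediction_mask_constant_is_empty(self):
        pred = PredictionImage(np.full((8, 8), 0.3))
        assert not prediction_mask(pred, method="otsu").any()


class TestTriage:
    def _pred_with_blob(self, value=0.9, size=20):
        img = np.zeros((96, 96))
        img[10:10 + size, 10:10 + size] = value
        return PredictionImage(img)

    def test_all_zero_predictions_negative(self):
        res = triage_fov([PredictionImage(np.zeros((96, 96)))])
        assert not res.consensus
        assert res.per_model_votes == (False,)

    def test_disagreement_means_negative(self):
        """One dissenting model vetoes the FOV (false-positive control)."""
        pos = self._pred_with_blob()
        neg = PredictionImage(np.zeros((96, 96)))
        res = triage_fov([pos, neg])
        assert res.per_model_votes == (True, False)
        assert not res.consensus

    def test_small_component_below_area_floor(self):
        # 2 um^2 ~ 162 px at 0.111 um pixels -> 12x13 block is too small
        small = self._pred_with_blob(size=13)
        assert not triage_fov([small], min_area_um2=3.0).consensus
        big = self._pred_with_blob(size=20)  # ~4.9 um^2
        res = triage_fov([big], min_area_um2=3.0)
        assert res.consensus and res.aggregate_count == 1


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, rng):
        net, _ = build_unet(TOY_MODEL)
        path = tmp_path / "weights.npz"
        save_model(net, path)
        loaded = load_model(path)
        stack = PlaneStack(rng.random((1, 32, 32)).astype(np.float32),
                           OpticalConfig(n_planes=1))
        np.testing.assert_array_equal(predict(net, stack).values,
                                      predict(loaded, stack).values)
        assert loaded.fingerprint() == net.fingerprint()


class TestRegressionClassificationConsistency:
    def test_matched_models_agree_on_masks(self):
        """Otsu masks of regression outputs track the classification
        model's 0.5-cut masks (Jaccard >= 0.6) after matched training."""
        from phasestain.datasets import make_virtual_staining_pairs
        from phasestain.metrics import overlap_metrics
        from phasestain.prep import split_dataset

        # smaller matched models keep this a quick check
        pairs = make_virtual_staining_pairs(48, seed=3)
        ids = [p.acquisition_id for p in pairs]
        split = split_dataset(ids, seed=0)
        tcfg = TrainConfig(max_epochs=6, batch_size=4, early_stop_patience=6,
                           seed=0)
        small = dict(in_planes=1, base_features=8, depth=4, seed=0)
        reg, _ = train_model(pairs, split, ModelConfig(mode="regression", **small), tcfg)
        cls, _ = train_model(pairs, split, ModelConfig(mode="classification", **small), tcfg)

        by_id = {p.acquisition_id: p for p in pairs}
        jacs = []
        for tid in split.test_ids:
            stack = by_id[tid].input_stack
            m_reg = prediction_mask(predict(reg, stack), method="otsu")
            m_cls = prediction_mask(predict(cls, stack), method="fixed")
            if not (m_reg.any() or m_cls.any()):
                continue
            j, _, _ = overlap_metrics(m_reg, m_cls)
            jacs.append(j)
        assert np.mean(jacs) >= 0.6
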