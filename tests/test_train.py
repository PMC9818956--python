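"""Two-stage training pipeline: optimization, transfer, determinism."""

import numpy as np
import pytest

from penreg.homography import PairedLandmarks
from penreg.nn import NetworkConfig, build_network, predict_field
from penreg.train import (
    DatasetSplit,
    TrainConfig,
    fine_tune,
    register_pair,
    train_unsupervised,
    transfer_weights,
)


def tiny_config(size=16):
    return NetworkConfig(
        levels=2, filters_per_level=(4, 8), input_size=(size, size), dtype="float64"
    )


def self_pairs(rng, n=4, size=16):
    """Pairs with fixed == moving: the zero field is an optimum."""
    out = []
    for _ in range(n):
        img = rng.random((size, size))
        out.append((img, img.copy()))
    return out


class TestTrainConfig:
    def test_lr_schedule_constant_then_linear(self):
        cfg = TrainConfig(learning_rate=1e-3, epochs=10, decay_start_epoch=5)
        assert cfg.lr_at(0) == cfg.lr_at(4) == 1e-3
        assert cfg.lr_at(5) == pytest.approx(1e-3)
        assert cfg.lr_at(7) == pytest.approx(1e-3 * 3 / 5)
        assert cfg.lr_at(10) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=5, decay_start_epoch=9)

    def test_paper_scale_schedule(self):
        cfg = TrainConfig.paper_scale()
        assert cfg.learning_rate == 1e-4
        assert cfg.batch_size == 4
        assert (cfg.epochs, cfg.decay_start_epoch) == (200, 100)


class TestTrainUnsupervised:
    def test_loss_decreases_on_self_pairs(self, rng):
        model = build_network(tiny_config(), seed=1)
        pairs = self_pairs(rng)
        _, trace = train_unsupervised(model, pairs, TrainConfig(epochs=1, seed=0))
        model2 = build_network(tiny_config(), seed=1)
        _, trace10 = train_unsupervised(model2, pairs, TrainConfig(epochs=10, seed=0))
        assert trace10[-1] <= trace10[0]
        assert model.training_phase == "unsupervised"

    def test_empty_dataset_rejected(self):
        model = build_network(tiny_config(), seed=1)
        with pytest.raises(ValueError, match="empty"):
            train_unsupervised(model, [], TrainConfig(epochs=1))

    def test_seeded_runs_bit_identical(self, rng):
        pairs = self_pairs(rng, n=6)
        traces = []
        for _ in range(2):
            model = build_network(tiny_config(), seed=3)
            _, trace = train_unsupervised(model, pairs, TrainConfig(epochs=3, seed=9))
            traces.append((trace, model.checksum()))
        assert traces[0][0] == traces[1][0]
        assert traces[0][1] == traces[1][1]


class TestTransferWeights:
    def test_checksums_equal_after_transfer(self):
        src = build_network(tiny_config(), seed=5)
        tgt = transfer_weights(src, tiny_config())
        assert tgt.checksum() == src.checksum()
        assert tgt.training_phase == "transferred"

    def test_mismatched_filters_rejected(self):
        src = build_network(tiny_config(), seed=5)
        other = NetworkConfig(
            levels=2, filters_per_level=(4, 16), input_size=(16, 16), dtype="float64"
        )
        with pytest.raises(ValueError, match="mismatch"):
            transfer_weights(src, other)

    def test_finetune_step_with_tiny_lr_keeps_params(self, rng):
        """After transfer, a fine-tune run with a vanishing learning rate
        leaves the parameters effectively unchanged."""
        src = build_network(tiny_config(), seed=5)
        tgt = transfer_weights(src, tiny_config())
        img = rng.random((16, 16))
        lms = PairedLandmarks([(8.0, 8.0)], [(8.0, 8.0)], ["background"])
        before = tgt.theta
        fine_tune(tgt, [(img, img.copy(), lms)],
                  TrainConfig(learning_rate=1e-30, epochs=1, seed=0))
        after = tgt.theta
        for k in before:
            np.testing.assert_allclose(after[k], before[k], atol=1e-12)


class TestFineTune:
    def test_missing_landmarks_rejected(self, rng):
        model = build_network(tiny_config(), seed=2)
        with pytest.raises(ValueError, match="landmarks"):
            fine_tune(model, self_pairs(rng, n=2), TrainConfig(epochs=1))

    def test_mu_zero_matches_unsupervised_trace(self, rng):
        imgs = self_pairs(rng, n=4)
        lms = PairedLandmarks([(5.0, 5.0)], [(6.0, 6.0)], ["foreground"])
        annotated = [(f, m, lms) for f, m in imgs]
        cfg = TrainConfig(epochs=3, seed=11, mu=0.0)
        a = build_network(tiny_config(), seed=4)
        _, trace_ft = fine_tune(a, annotated, cfg)
        b = build_network(tiny_config(), seed=4)
        _, trace_un = train_unsupervised(b, annotated, cfg)
        assert trace_ft == trace_un
        assert a.checksum() == b.checksum()

    def test_phase_set(self, rng):
        model = build_network(tiny_config(), seed=2)
        img = rng.random((16, 16))
        lms = PairedLandmarks([(4.0, 4.0)], [(5.0, 4.0)], ["background"])
        fine_tune(model, [(img, img, lms)], TrainConfig(epochs=1))
        assert model.training_phase == "fine_tuned"


class TestFineTuneValidated:
    def test_warm_start_kept_without_evidence(self, rng):
        """When fine-tuning cannot demonstrate significant validation
        improvement, the returned parameters equal the warm start."""
        from penreg.train import fine_tune_validated

        src = build_network(tiny_config(), seed=8)
        start_sum = src.checksum()
        # self-pairs with already-aligned landmarks: nothing to improve
        pairs = []
        for _ in range(6):
            img = rng.random((16, 16))
            lms = PairedLandmarks([(7.0, 7.0), (4.0, 9.0)], [(7.0, 7.0), (4.0, 9.0)],
                                  ["foreground", "background"])
            pairs.append((img, img.copy(), lms))
        model, trace, info = fine_tune_validated(
            src, pairs, TrainConfig(learning_rate=1e-4, epochs=3, seed=1)
        )
        assert info["best_epoch"] == -1
        assert model.checksum() == start_sum
        assert model.training_phase == "fine_tuned"
        assert len(trace) == 3

    def test_split_sizes(self, rng):
        from penreg.train import fine_tune_validated

        src = build_network(tiny_config(), seed=8)
        img = rng.random((16, 16))
        lms = PairedLandmarks([(7.0, 7.0)], [(8.0, 7.0)], ["background"])
        pairs = [(img, img.copy(), lms)] * 10
        _, _, info = fine_tune_validated(
            src, pairs, TrainConfig(learning_rate=1e-6, epochs=1, seed=1)
        )
        assert info["n_val"] == 5 and info["n_fit"] == 5


class TestRegisterPair:
    def test_deterministic_and_shapes(self, rng):
        model = build_network(tiny_config(), seed=6)
        f, m = rng.random((16, 16)), rng.random((16, 16))
        field1, warped1 = register_pair(model, f, m)
        field2, warped2 = register_pair(model, f, m)
        assert field1.shape == (16, 16, 2) and warped1.shape == (16, 16)
        assert np.array_equal(field1, field2) and np.array_equal(warped1, warped2)

    def test_shape_mismatch(self, rng):
        model = build_network(tiny_config(), seed=6)
        with pytest.raises(ValueError):
            register_pair(model, rng.random((32, 32)), rng.random((32, 32)))


class TestDatasetSplit:
    def test_annotated_splits_require_landmarks(self, rng):
        img = rng.random((8, 8))
        with pytest.raises(ValueError, match="landmarks"):
            DatasetSplit(train_pairs=[], finetune_pairs=[(img, img)], test_pairs=[])
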