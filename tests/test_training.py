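"""Training loop bookkeeping, checkpointing, prediction and ablations."""

import numpy as np
import pytest

from refineseg import (Checkpoint, ConfigError, NetConfig, TrainConfig,
                       predict, run_ablation, samples_from_volumes, train)
from refineseg.training import Model


class TestConfig:
    def test_uncertainty_input_requires_an_auxiliary_decoder(self):
        with pytest.raises(ConfigError):
            TrainConfig(use_aux1=False, use_aux2=False,
                        use_uncertainty_input=True, use_refinement=True)

    def test_positivity_checks(self):
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)
        with pytest.raises(ConfigError):
            TrainConfig(learning_rate=-1)

    def test_plain_variant_allowed(self):
        cfg = TrainConfig(use_aux1=False, use_aux2=False,
                          use_uncertainty_input=False, use_refinement=False)
        assert not cfg.use_refinement


class TestBookkeeping:
    def test_history_length_and_steps(self, tiny_setup):
        samples = samples_from_volumes(tiny_setup["volumes"][:1],
                                       work_size=(32, 32))
        assert len(samples) == 4
        _, history = train(samples, tiny_setup["net"],
                           TrainConfig(epochs=2, seed=0),
                           work_size=(32, 32))
        assert len(history) == 2
        assert history.steps_per_epoch == [4, 4]
        assert all(np.isfinite(loss) for loss in history.epoch_loss)
        assert "main_ce" in history.epoch_terms[0]
        assert "refined_dice" in history.epoch_terms[0]

    def test_fixed_seed_reproduces_history(self, tiny_setup):
        samples = samples_from_volumes(tiny_setup["volumes"][:1],
                                       work_size=(32, 32))
        net = tiny_setup["net"]
        _, h1 = train(samples, net, TrainConfig(epochs=1, seed=5),
                      work_size=(32, 32))
        _, h2 = train(samples, net, TrainConfig(epochs=1, seed=5),
                      work_size=(32, 32))
        assert h1.epoch_loss == h2.epoch_loss

    def test_empty_training_set_rejected(self, tiny_setup):
        with pytest.raises(ValueError):
            train([], tiny_setup["net"], tiny_setup["train"])

    def test_history_csv(self, tiny_checkpoint, tmp_path):
        _, history = tiny_checkpoint
        out = tmp_path / "log.csv"
        history.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(history) + 1
        assert lines[0].startswith("epoch,total")


class TestCheckpoint:
    def test_roundtrip_predict_bit_identical(self, tiny_setup,
                                             tiny_checkpoint, tmp_path):
        ckpt, _ = tiny_checkpoint
        vol = tiny_setup["volumes"][2]
        before = predict(ckpt, vol.image)
        path = tmp_path / "model.npz"
        ckpt.save(path)
        again = Checkpoint.load(path)
        after = predict(again, vol.image)
        np.testing.assert_array_equal(before, after)

    def test_predict_deterministic(self, tiny_setup, tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        vol = tiny_setup["volumes"][2]
        a = predict(ckpt, vol.image)
        b = predict(ckpt, vol.image)
        np.testing.assert_array_equal(a, b)

    def test_no_refinement_checkpoint_has_no_refinement_weights(
            self, tiny_setup):
        samples = samples_from_volumes(tiny_setup["volumes"][:1],
                                       work_size=(32, 32))
        tcfg = TrainConfig(epochs=1, seed=0, use_refinement=False,
                           use_uncertainty_input=False)
        ckpt, _ = train(samples, tiny_setup["net"], tcfg,
                        work_size=(32, 32))
        assert ckpt.ref_state is None

    def test_zeroed_residual_head_equals_main_decoder_argmax(
            self, tiny_setup, tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        model = ckpt.build_model()
        model.ref.zero_head()
        vol = tiny_setup["volumes"][2]
        sample_img = np.random.default_rng(0).random((32, 32))
        with_ref, _ = model.predict_slice(sample_img, slice_seed=3,
                                          refine=True)
        without, _ = model.predict_slice(sample_img, slice_seed=3,
                                         refine=False)
        np.testing.assert_array_equal(with_ref, without)

    def test_prediction_shape_matches_input_volume(self, tiny_setup,
                                                   tiny_checkpoint):
        ckpt, _ = tiny_checkpoint
        vol = tiny_setup["volumes"][2]
        labels, unc = predict(ckpt, vol.image, return_uncertainty=True)
        assert labels.shape == vol.image.shape
        assert unc.shape == vol.image.shape
        assert set(np.unique(labels)) <= {0, 1, 2}


class TestModelVariants:
    def test_plain_variant_is_encoder_plus_main_decoder_only(self):
        net_cfg = NetConfig(base_channels=2, depth=3, seed=0)
        plain = Model(net_cfg, TrainConfig(
            use_aux1=False, use_aux2=False, use_refinement=False,
            use_uncertainty_input=False))
        full = Model(net_cfg, TrainConfig())
        plain_names = set(plain.named_parameters())
        full_names = set(full.named_parameters())
        assert plain_names < full_names
        assert all(n.startswith(("encoder.", "dec_main."))
                   for n in plain_names)
        dropped = full_names - plain_names
        assert any(n.startswith("dec_aux1.") for n in dropped)
        assert any(n.startswith("ref.") for n in dropped)

    def test_loss_decreases_on_tiny_noiseless_problem(self):
        from refineseg import PhantomConfig, OrganSpec, generate_phantom
        spec = OrganSpec(name="disc", mean_hu=-760.0, boundary_delta=800.0,
                         size_frac=(0.08, 0.15), shape_jitter=0.1)
        vol = generate_phantom(PhantomConfig(
            n_classes=2, organ_specs=[spec], noise_sd=0.0, seed=3,
            n_slices=4, height=32, width=32))
        samples = samples_from_volumes([vol], work_size=(32, 32))
        net = NetConfig(n_classes=2, base_channels=4, depth=3, seed=0)
        _, history = train(samples, net, TrainConfig(epochs=4, seed=0),
                           work_size=(32, 32))
        assert history.epoch_loss[-1] < history.epoch_loss[0]


class TestAblation:
    def test_grid_produces_one_row_per_configuration(self, tiny_setup):
        grid = [
            {"use_refinement": False, "use_uncertainty_input": False,
             "use_aux1": False, "use_aux2": False},
            {"noise_kind": "gaussian"},
        ]
        rows = run_ablation(grid, tiny_setup["volumes"][:1],
                            tiny_setup["volumes"][2:], tiny_setup["net"],
                            TrainConfig(epochs=1, seed=0),
                            work_size=(32, 32))
        assert len(rows) == 2
        for row in rows:
            assert "dice_1" in row and "dice_2" in row
            assert np.isfinite(row["dice_1"])

    def test_unknown_key_rejected(self, tiny_setup):
        with pytest.raises(ConfigError, match="unknown"):
            run_ablation([{"bogus": 1}], tiny_setup["volumes"][:1],
                         tiny_setup["volumes"][2:], tiny_setup["net"],
                         TrainConfig(epochs=1, seed=0), work_size=(32, 32))
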