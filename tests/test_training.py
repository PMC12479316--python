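"""GAN training loop: step isolation, determinism, validation hygiene."""

import numpy as np
import pytest

from attnfnet.config import tiny_experiment_config
from attnfnet.losses import LossConfig
from attnfnet.model import PatchGANDiscriminator
from attnfnet.nn import Adam
from attnfnet.synthetic import generate_dataset
from attnfnet.training import (TrainConfig, build_generator, fit,
                               load_checkpoint, predict, prepare_data,
                               save_checkpoint, train_step)

MICRO = tiny_experiment_config(0)


def _params_hash(module):
    return [p.data.tobytes() for p in module.parameters()]


@pytest.fixture(scope="module")
def micro_setup(small_dataset, small_prepared):
    G = build_generator(MICRO.model, "attnfnet", seed=1)
    D = PatchGANDiscriminator(MICRO.disc, seed=2)
    return G, D


class TestTrainStep:
    def test_zero_learning_rate_leaves_parameters_unchanged(
            self, micro_setup, small_prepared):
        G, D = micro_setup
        x, y, _ = small_prepared.splits["train"][0]
        og = Adam(G.parameters(), lr=0.0)
        od = Adam(D.parameters(), lr=0.0)
        hg, hd = _params_hash(G), _params_hash(D)
        m = train_step(x, y, G, D, og, od, LossConfig())
        assert np.isfinite(m["loss_g"]) and np.isfinite(m["loss_d"])
        assert _params_hash(G) == hg and _params_hash(D) == hd

    def test_one_step_updates_both_players(self, small_prepared):
        G = build_generator(MICRO.model, "attnfnet", seed=3)
        D = PatchGANDiscriminator(MICRO.disc, seed=4)
        x, y, _ = small_prepared.splits["train"][0]
        og, od = Adam(G.parameters(), lr=1e-3), Adam(D.parameters(), lr=1e-3)
        hg, hd = _params_hash(G), _params_hash(D)
        train_step(x, y, G, D, og, od, LossConfig())
        assert _params_hash(G) != hg
        assert _params_hash(D) != hd

    def test_player_updates_are_isolated(self, small_prepared):
        """The D update must leave G bit-identical, and vice versa."""
        x, y, _ = small_prepared.splits["train"][0]
        from attnfnet.losses import discriminator_loss, generator_loss
        from attnfnet.nn import Tensor

        G = build_generator(MICRO.model, "attnfnet", seed=5)
        D = PatchGANDiscriminator(MICRO.disc, seed=6)
        og, od = Adam(G.parameters(), lr=1e-3), Adam(D.parameters(), lr=1e-3)

        fake = G(x)
        hg = _params_hash(G)
        od.zero_grad()
        discriminator_loss(D.probability_map(x, Tensor(y)),
                           D.probability_map(x, fake.detach())).backward()
        od.step()
        assert _params_hash(G) == hg          # D step cannot move G

        hd = _params_hash(D)
        og.zero_grad()
        D.zero_grad()
        generator_loss(D.probability_map(x, fake), Tensor(y), fake).backward()
        og.step()
        assert _params_hash(D) == hd          # G step cannot move D


@pytest.fixture(scope="module")
def micro_fit(small_dataset, small_prepared):
    cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=7,
                      checkpoint_every=5)
    return fit(small_dataset, cfg, MICRO.loss, MICRO.model, MICRO.disc,
               prepared=small_prepared)


class TestFit:
    def test_history_has_one_record_per_epoch(self, micro_fit):
        _, _, hist = micro_fit
        assert len(hist) == 2
        assert [r["epoch"] for r in hist.records] == [1, 2]
        for r in hist.records:
            assert {"loss_g", "loss_d", "val_mse", "val_ssim"} <= set(r)

    def test_rerun_is_bit_identical(self, small_dataset, small_prepared,
                                    micro_fit):
        G1, _, h1 = micro_fit
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, seed=7,
                          checkpoint_every=5)
        G2, _, h2 = fit(small_dataset, cfg, MICRO.loss, MICRO.model,
                        MICRO.disc, prepared=small_prepared)
        assert h1.records == h2.records
        assert _params_hash(G1) == _params_hash(G2)

    def test_checkpoint_round_trip(self, micro_fit, tmp_path, small_prepared):
        G, _, _ = micro_fit
        cfg = TrainConfig(seed=7)
        save_checkpoint(G, MICRO.model, cfg, tmp_path / "ck")
        G2, meta = load_checkpoint(tmp_path / "ck")
        assert meta["n_parameters"] == G.n_parameters()
        x, _, _ = small_prepared.splits["val"][0]
        np.testing.assert_array_equal(G(x).data, G2(x).data)

    def test_empty_val_split_rejected(self, small_prepared):
        ds = generate_dataset(3, 1, (1.0, 0.0, 0.0), seed=0,
                              grid_shape=(64, 56))
        with pytest.raises(ValueError, match="nonempty"):
            fit(ds, TrainConfig(epochs=1), MICRO.loss, MICRO.model, MICRO.disc)


class TestTrainingHygiene:
    def test_perceptual_term_dominates_adversarial_at_init(self,
                                                           small_prepared):
        """With default weights the lambda-scaled SSIM+L2 term should exceed
        the adversarial term by at least 10x at initialization — the design
        intent of lambda = 100."""
        from attnfnet.losses import LossConfig, ssiml2_loss
        from attnfnet.nn import Tensor

        G = build_generator(MICRO.model, "attnfnet", seed=8)
        D = PatchGANDiscriminator(MICRO.disc, seed=9)
        cfg = LossConfig()
        x, y, _ = small_prepared.splits["train"][0]
        fake = G(x)
        adv = -np.log(np.clip(D.probability_map(x, fake).data, 1e-7,
                              1 - 1e-7)).mean()
        perceptual = cfg.lambda_adv * ssiml2_loss(Tensor(y), fake, cfg).item()
        assert perceptual > 10.0 * adv

    def test_validation_pass_mutates_nothing(self, small_prepared):
        from attnfnet.training import _validate

        G = build_generator(MICRO.model, "attnfnet", seed=10)
        og = Adam(G.parameters(), lr=1e-3)
        before = (_params_hash(G), og.state_hash())
        _validate(G, small_prepared.splits["val"], MICRO.loss)
        assert (_params_hash(G), og.state_hash()) == before


class TestPredict:
    def test_contract(self, micro_setup, small_dataset, small_prepared):
        G, _ = micro_setup
        s = small_dataset.subset("test")[0]
        a = predict(G, s.depth, small_prepared)
        b = predict(G, s.depth, small_prepared)
        assert a.shape == (27, 64)
        assert (a >= 0).all()
        np.testing.assert_array_equal(a, b)   # deterministic in evaluation
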