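import numpy as np
import pytest

from uvsynth import nn
from uvsynth import uv_photo_net as U


class ConstantDisc:
    """Discriminator stub returning a fixed probability."""

    def __init__(self, p):
        self.p = p

    def forward(self, cond, cand):
        return np.full(cond.shape[0], self.p)


def _batch(rng, n=4, s=16):
    x = rng.random((n, 3, s, s)).astype(np.float32)
    y = rng.random((n, 1, s, s)).astype(np.float32)
    return x, y


class TestGeneratorForward:
    def test_deterministic_in_inference_mode(self, rng):
        gen = U.build_generator(U.GeneratorConfig(input_size=16,
                                                  base_channels=4, depth=2))
        patch = rng.random((16, 16, 3))
        np.testing.assert_array_equal(U.generator_forward(gen, patch),
                                      U.generator_forward(gen, patch))

    def test_output_bounded_and_same_shape(self, rng):
        gen = U.build_generator(U.GeneratorConfig(input_size=16,
                                                  base_channels=4, depth=2))
        out = U.generator_forward(gen, rng.random((16, 16, 3)) * 10 - 5)
        assert out.shape == (16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_innermost_encoding_size(self, rng):
        gen = U.build_generator(U.GeneratorConfig(input_size=64, depth=3,
                                                  base_channels=4))
        U.generator_forward(gen, rng.random((64, 64, 3)))
        assert gen._trace[-1][2:] == (8, 8)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            U.build_generator(U.GeneratorConfig(input_size=60, depth=3))
        with pytest.raises(ValueError):
            U.build_generator(U.GeneratorConfig(dropout_rate=1.0))


class TestObjectiveAlgebra:
    def test_zero_lambda_zero_residual(self, rng):
        x, y = _batch(rng)
        loss, terms = U.generator_loss(x, y, y.copy(), None, lam=0.0)
        assert loss == 0.0 and terms.l1_term == 0.0

    def test_zero_lambda_reduces_to_pure_l1(self, rng):
        x, y = _batch(rng)
        g = np.clip(y + 0.1, None, None)
        loss, terms = U.generator_loss(x, y, g, None, lam=0.0)
        assert loss == pytest.approx(0.1, abs=1e-6)
        assert terms.adv_gen_term == 0.0

    def test_adversarial_term_with_half_stub(self, rng):
        x, y = _batch(rng)
        g = y + 0.05
        loss, terms = U.generator_loss(x, y, g, ConstantDisc(0.5), lam=0.005)
        assert loss == pytest.approx(0.05 + 0.005 * np.log(0.5), abs=1e-6)
        assert terms.adv_gen_term == pytest.approx(0.005 * np.log(0.5))

    def test_empty_batch_and_negative_lambda_rejected(self, rng):
        x, y = _batch(rng)
        with pytest.raises(ValueError):
            U.generator_loss(x[:0], y[:0], y[:0], None, lam=0.0)
        with pytest.raises(ValueError):
            U.generator_loss(x, y, y, None, lam=-0.1)

    def test_disc_loss_half_stub_is_two_log_two(self, rng):
        x, y = _batch(rng)
        loss = U.discriminator_loss(x, y + 0.1, x, y, ConstantDisc(0.5))
        assert loss == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_disc_loss_perfect_and_antiperfect_limits(self, rng):
        x, y = _batch(rng)
        eps = U.LOG_EPS

        class Perfect:
            def forward(self, cond, cand):
                fake = np.abs(cand - (y + 0.1)).max() < 1e-9
                return np.full(cond.shape[0], eps if fake else 1 - eps)

        class AntiPerfect(Perfect):
            def forward(self, cond, cand):
                return 1.0 - Perfect.forward(self, cond, cand)

        assert U.discriminator_loss(x, y + 0.1, x, y, Perfect()) == \
            pytest.approx(0.0, abs=1e-5)
        anti = U.discriminator_loss(x, y + 0.1, x, y, AntiPerfect())
        assert anti == pytest.approx(2 * np.log(1 / eps), rel=1e-6)

    def test_overlapping_index_sets_rejected(self, rng):
        x, y = _batch(rng)
        with pytest.raises(ValueError):
            U.discriminator_loss(x, y, x, y, ConstantDisc(0.5),
                                 fake_idx=[0, 1], real_idx=[1, 2])


class TestTrainingDynamics:
    def test_single_step_decreases_generator_loss(self, rng):
        gen = U.build_generator(U.GeneratorConfig(input_size=16, depth=2,
                                                  base_channels=4,
                                                  dropout_rate=0.0))
        x, y = _batch(rng, n=1)
        opt = nn.Adam(gen.layers(), lr=1e-3)
        before = U.generator_loss(x, y, gen.forward(x), None, 0.0)[0]
        U._gen_step(gen, None, opt, x, y, 0.0, np.random.default_rng(0))
        after = U.generator_loss(x, y, gen.forward(x), None, 0.0)[0]
        assert after < before

    def _quick_schedule(self, iters=25):
        return U.TrainSchedule(joint_iters=iters, disc_only_iters=4,
                               gen_only_iters=6, val_every=10, batch_size=4)

    def _quick_config(self):
        return U.GeneratorConfig(input_size=16, depth=2, base_channels=4)

    def _toy_patches(self, rng, n=24, s=16):
        x = rng.random((n, s, s, 3))
        y = x.mean(axis=3)
        return (x[:16], y[:16]), (x[16:], y[16:])

    def test_same_seed_reproduces_losses(self, rng):
        tr, va = self._toy_patches(rng)
        runs = [U.train(tr, va, self._quick_config(), self._quick_schedule(),
                        lam=0.005, seed=7) for _ in range(2)]
        assert runs[0].val_l1_trace == runs[1].val_l1_trace
        assert runs[0].best_val_l1 == runs[1].best_val_l1

    def test_lambda_changes_trajectory(self, rng):
        tr, va = self._toy_patches(rng)
        a = U.train(tr, va, self._quick_config(), self._quick_schedule(),
                    lam=0.0, seed=7)
        b = U.train(tr, va, self._quick_config(), self._quick_schedule(),
                    lam=0.005, seed=7)
        assert a.val_l1_trace != b.val_l1_trace
        assert b.disc is not None and a.disc is None

    def test_validation_l1_improves_on_learnable_task(self, rng):
        tr, va = self._toy_patches(rng, n=40)
        st = U.train(tr, va, self._quick_config(),
                     U.TrainSchedule(joint_iters=120, disc_only_iters=0,
                                     gen_only_iters=0, val_every=40,
                                     batch_size=8), lam=0.0, seed=1)
        assert st.val_l1_trace[-1][1] < st.val_l1_trace[0][1]
        assert st.best_val_l1[0] <= st.val_l1_trace[0][1]

    def test_empty_validation_warns_and_disables_early_stop(self, rng):
        tr, _ = self._toy_patches(rng)
        with pytest.warns(UserWarning):
            st = U.train(tr, None, self._quick_config(),
                         self._quick_schedule(10), lam=0.0, seed=1)
        assert st.best_val_l1 is None

    def test_checkpoint_round_trip(self, rng, tmp_path):
        tr, va = self._toy_patches(rng)
        st = U.train(tr, va, self._quick_config(), self._quick_schedule(10),
                     lam=0.005, seed=3)
        U.save_state(st, tmp_path / "ckpt")
        back = U.load_state(tmp_path / "ckpt")
        x = rng.random((1, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(st.gen.forward(x), back.gen.forward(x))
        assert back.lam == 0.005 and back.best_val_l1 == st.best_val_l1


class _IdentityGen:
    """Stub generator: channel-mean of the input patch."""

    def forward(self, x, train=False, rng=None):
        return x.mean(axis=1, keepdims=True)


class TestConvertImage:
    def test_identity_stub_passes_channel_mean_through(self, rng):
        img = rng.random((64, 64, 3))
        out = U.convert_image(_IdentityGen(), img, patch_size=32)
        np.testing.assert_allclose(out, img.mean(axis=2), atol=1e-6)

    def test_disjoint_and_overlapping_grids_agree_on_constant_input(self):
        img = np.full((64, 64, 3), 0.4)
        a = U.convert_image(_IdentityGen(), img, patch_size=32, stride=32)
        b = U.convert_image(_IdentityGen(), img, patch_size=32, stride=16)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_uncovered_pixels_fall_back_to_grayscale(self, rng):
        from uvsynth.baselines import grayscale

        img = rng.random((64, 64, 3))
        mask = np.zeros((64, 64), bool)
        mask[:32, :32] = True            # only the top-left window is kept
        out = U.convert_image(_IdentityGen(), img, face_map=mask,
                              patch_size=32, min_mask_fraction=0.5)
        np.testing.assert_allclose(out[40:, 40:], grayscale(img)[40:, 40:])
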