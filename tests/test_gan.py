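"""GAN components: stage schedule, fade-in blending, Wasserstein losses with
gradient penalty (analytic critics), architecture audits, and tiny training
runs."""

import numpy as np
import pytest

from fibropath import gan
from fibropath.gan import (
    DCGANDiscriminator,
    DCGANGenerator,
    GanTrainConfig,
    InvalidConfigError,
    PGGANGenerator,
    StageSchedule,
    architecture_summary,
    build_stage_schedule,
    critic_loss,
    fade_in_blend,
    generator_loss,
    gradient_penalty,
    sample_images,
    train_dcgan,
    train_pggan,
)
from fibropath.nn import tensor as T
from fibropath.nn.tensor import Tensor


class TestStageSchedule:
    def test_default_grows_to_256_in_seven_stages(self):
        sched = build_stage_schedule(4, 256)
        assert sched.resolutions == (4, 8, 16, 32, 64, 128, 256)
        assert sched.n_stages == 7
        assert sched.n_growth_events == 6

    def test_degenerate_and_partial_schedules(self):
        assert build_stage_schedule(4, 4).resolutions == (4,)
        assert build_stage_schedule(8, 32).resolutions == (8, 16, 32)

    def test_each_entry_doubles(self):
        res = build_stage_schedule(4, 128).resolutions
        assert all(b == 2 * a for a, b in zip(res, res[1:]))

    @pytest.mark.parametrize("start,target", [(3, 256), (4, 100), (64, 32)])
    def test_invalid_configs_rejected(self, start, target):
        with pytest.raises(InvalidConfigError):
            build_stage_schedule(start, target)


class TestFadeIn:
    def test_endpoints_exact(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 3, 4, 4)), rng.normal(size=(2, 3, 4, 4))
        assert np.array_equal(fade_in_blend(a, b, 0.0), a)
        assert np.array_equal(fade_in_blend(a, b, 1.0), b)

    def test_midpoint_of_constants(self):
        a = np.zeros((1, 3, 2, 2))
        b = np.ones((1, 3, 2, 2))
        np.testing.assert_allclose(fade_in_blend(a, b, 0.5), 0.5)

    def test_linear_in_alpha(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        for alpha in (0.25, 0.5, 0.75):
            np.testing.assert_allclose(
                fade_in_blend(a, b, alpha), (1 - alpha) * a + alpha * b
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fade_in_blend(np.zeros((2, 2)), np.zeros((3, 3)), 0.5)


class TestWassersteinLosses:
    def test_unit_gradient_critic_has_zero_penalty(self):
        critic = lambda x: T.tsum(x, axis=1)  # gradient norm 1 for d=1
        batch = np.random.default_rng(0).normal(size=(8, 1))
        assert gradient_penalty(critic, batch, batch + 1.0, 10.0).item() < 1e-6

    def test_constant_critic_penalty_is_lambda(self):
        critic = lambda x: T.tsum(x * 0.0, axis=1)
        batch = np.zeros((4, 3))
        assert gradient_penalty(critic, batch, batch + 1.0, 10.0).item() == pytest.approx(
            10.0, rel=1e-4
        )

    def test_scaled_sum_critic_closed_form(self):
        d = 4
        critic = lambda x: T.tsum(x * 2.0, axis=1)  # gradient norm 2*sqrt(d)
        rng = np.random.default_rng(1)
        penalty = gradient_penalty(
            critic, rng.normal(size=(6, d)), rng.normal(size=(6, d)), 10.0
        )
        assert penalty.item() == pytest.approx(10.0 * (2 * np.sqrt(d) - 1) ** 2, rel=1e-5)

    def test_constant_critic_loss_is_lambda(self):
        critic = lambda x: T.tsum(x * 0.0, axis=1) + Tensor(3.0)
        batch = np.zeros((4, 2))
        assert critic_loss(critic, batch, batch + 1.0, 10.0).item() == pytest.approx(
            10.0, rel=1e-4
        )

    def test_sum_critic_without_penalty_is_mean_difference(self):
        critic = lambda x: T.tsum(x, axis=1)
        real = np.array([[1.0, 2.0], [3.0, 4.0]])
        fake = np.array([[0.0, 1.0], [1.0, 0.0]])
        expected = fake.sum(axis=1).mean() - real.sum(axis=1).mean()
        assert critic_loss(critic, real, fake, 0.0).item() == pytest.approx(expected)

    def test_identical_batches_zero_loss_without_penalty(self):
        critic = lambda x: T.tsum(x ** 2, axis=1)
        batch = np.random.default_rng(2).normal(size=(5, 3))
        assert critic_loss(critic, batch, batch, 0.0).item() == pytest.approx(0.0)

    def test_generator_loss(self):
        const = lambda x: T.tsum(x * 0.0, axis=1) + Tensor(2.5)
        assert generator_loss(const, np.zeros((3, 2))).item() == pytest.approx(-2.5)
        sum_critic = lambda x: T.tsum(x, axis=1)
        assert generator_loss(sum_critic, np.zeros((3, 2))).item() == 0.0
        fake = np.array([[1.0, 2.0], [3.0, 5.0]])
        assert generator_loss(sum_critic, fake).item() == pytest.approx(-5.5)


class TestArchitectureAudits:
    def test_dcgan_layer_counts(self):
        rng = np.random.default_rng(0)
        cfg = GanTrainConfig(base_channels=32)
        gen = DCGANGenerator(32, cfg, rng)
        disc = DCGANDiscriminator(32, cfg, rng)
        gs = architecture_summary(gen)
        assert gs["conv"] == 5 and gs["scaling"] == 4
        ds = architecture_summary(disc)
        assert ds["conv"] == 6 and ds["fc"] == 1

    def test_latent_dim_default_is_128(self):
        assert GanTrainConfig().latent_dim == 128

    def test_generator_resolution_doubles_per_stage(self):
        rng = np.random.default_rng(0)
        cfg = GanTrainConfig(base_channels=16)
        sched = build_stage_schedule(4, 16)
        gen = PGGANGenerator(sched, cfg, rng)
        z = Tensor(rng.standard_normal((2, cfg.latent_dim)))
        for stage, res in enumerate(sched.resolutions):
            with T.no_grad():
                out = gen(z, stage=stage)
            assert out.shape == (2, 3, res, res)


class TestTraining:
    def test_pggan_smoke_and_determinism(self, fibrotic_patches16):
        data = np.stack(
            [p.reshape(8, 2, 8, 2, 3).mean(axis=(1, 3)) for p in fibrotic_patches16[:20]]
        ).astype(np.uint8)
        cfg = GanTrainConfig(
            epochs=2, batch_size=4, lr=1e-3, base_channels=16, seed=7
        )
        sched = build_stage_schedule(4, 8)
        state_a = train_pggan(data, cfg, sched)
        state_b = train_pggan(data, cfg, sched)
        assert [e["d_loss"] for e in state_a.log] == [e["d_loss"] for e in state_b.log]

        # alpha ramps are non-decreasing within each growth stage and end at 1
        for stage in range(1, sched.n_stages):
            alphas = [e["alpha"] for e in state_a.log if e["stage"] == stage]
            assert all(b >= a for a, b in zip(alphas, alphas[1:]))
            assert alphas[-1] == 1.0

    def test_sampling_contract(self, fibrotic_patches16):
        cfg = GanTrainConfig(epochs=1, batch_size=4, base_channels=16, seed=0)
        state = train_pggan(fibrotic_patches16[:8], cfg, build_stage_schedule(4, 16))
        imgs = sample_images(state, 5, seed=3)
        assert imgs.shape == (5, 16, 16, 3) and imgs.dtype == np.uint8
        assert np.array_equal(sample_images(state, 1, seed=9), sample_images(state, 1, seed=9))
        with pytest.raises(ValueError):
            sample_images(state, 0, seed=1)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_pggan(np.zeros((0, 8, 8, 3), dtype=np.uint8), GanTrainConfig(epochs=1))

    def test_resolution_mismatch_rejected(self, fibrotic_patches16):
        with pytest.raises(ValueError):
            train_pggan(
                fibrotic_patches16[:4],
                GanTrainConfig(epochs=1),
                build_stage_schedule(4, 8),
            )

    def test_dcgan_tiny_run_emits_samples(self, fibrotic_patches16):
        data = np.stack(
            [
                np.asarray(p).repeat(2, axis=0).repeat(2, axis=1)
                for p in fibrotic_patches16[:8]
            ]
        )  # 32x32
        cfg = gan.dcgan_defaults(epochs=1, batch_size=4, base_channels=16, seed=1)
        state = train_dcgan(data, cfg)
        imgs = sample_images(state, 3, seed=0)
        assert imgs.shape == (3, 32, 32, 3)

    def test_generated_samples_lean_toward_training_class(
        self, fibrotic_patches16, inflammatory_patches16
    ):
        """Distribution-shift check: a linear colour classifier fit on real
        patches assigns most generated samples to the GAN's training class."""
        from sklearn.linear_model import LogisticRegression

        def mean_rgb(batch):
            return batch.reshape(len(batch), -1, 3).mean(axis=1)

        X = np.concatenate(
            [mean_rgb(fibrotic_patches16), mean_rgb(inflammatory_patches16)]
        )
        y = np.concatenate(
            [np.ones(len(fibrotic_patches16)), np.zeros(len(inflammatory_patches16))]
        )
        clf = LogisticRegression(max_iter=500).fit(X, y)

        cfg = GanTrainConfig(epochs=50, batch_size=8, lr=1e-3, base_channels=32, seed=3)
        state = train_pggan(fibrotic_patches16, cfg, build_stage_schedule(4, 16))
        samples = sample_images(state, 128, seed=5)
        assigned = clf.predict(mean_rgb(samples))
        assert assigned.mean() > 0.5
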