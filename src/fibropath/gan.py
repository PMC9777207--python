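"""Progressive-growing GAN with WGAN-GP training, plus a DCGAN baseline.

The generator starts at 4x4 and is grown by doubling the resolution, two
convolution layers per growth event, until the target edge (256 by default:
seven resolution stages, six growth events). During each growth the new
high-resolution branch is faded in linearly: the output is
``(1 - alpha) * upsample(previous stage) + alpha * new branch`` with alpha
ramping 0 -> 1 over the first part of the stage.

Training follows WGAN-GP: the critic minimises
``mean C(fake) - mean C(real) + lambda * mean (||grad_xhat C(xhat)|| - 1)^2``
with xhat drawn uniformly on segments between real and fake samples, and the
generator minimises ``-mean C(fake)``. Adam with lr 1e-5, beta1 0.9,
beta2 0.999 and 50 epochs total (split evenly across stages) are the
reference settings; the penalty coefficient defaults to the WGAN-GP
reference value lambda = 10.

One GAN is trained per class; sampling a trained generator yields synthetic
patches used to pretrain the classifier.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import layers as L
from .nn import tensor as T
from .nn.optim import Adam
from .nn.tensor import Tensor, grad, no_grad


class InvalidConfigError(ValueError):
    pass


# -- schedule ----------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StageSchedule:
    """Ordered list of square resolutions, each double the previous."""

    resolutions: tuple[int, ...]

    @property
    def n_stages(self) -> int:
        return len(self.resolutions)

    @property
    def n_growth_events(self) -> int:
        return len(self.resolutions) - 1

    @property
    def target_res(self) -> int:
        return self.resolutions[-1]


def build_stage_schedule(start_res: int = 4, target_res: int = 256) -> StageSchedule:
    def _pow2(n):
        return n >= 1 and (n & (n - 1)) == 0

    if not (_pow2(start_res) and _pow2(target_res)):
        raise InvalidConfigError("resolutions must be powers of two")
    if start_res > target_res:
        raise InvalidConfigError("start_res must not exceed target_res")
    res = []
    r = start_res
    while r <= target_res:
        res.append(r)
        r *= 2
    return StageSchedule(tuple(res))


# -- configuration -----------------------------------------------------------

@dataclasses.dataclass
class GanTrainConfig:
    """Reference training settings; tests override toward desk scale."""

    latent_dim: int = 128
    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 50
    gp_lambda: float = 10.0
    batch_size: int = 16
    fade_in_fraction: float = 0.5
    seed: int = 0
    base_channels: int = 128     # channels at 4x4; halved per doubling, floor 8
    n_critic: int = 1            # critic updates per generator update
    use_pixelnorm: bool = False
    use_minibatch_stddev: bool = False

    def validate(self) -> "GanTrainConfig":
        if self.lr <= 0:
            raise InvalidConfigError("lr must be positive")
        if not 0.0 <= self.fade_in_fraction <= 1.0:
            raise InvalidConfigError("fade_in_fraction must be in [0, 1]")
        if self.gp_lambda < 0:
            raise InvalidConfigError("gp_lambda must be >= 0")
        if self.latent_dim < 1 or self.batch_size < 1 or self.epochs < 1:
            raise InvalidConfigError("latent_dim, batch_size, epochs must be >= 1")
        return self


def dcgan_defaults(**overrides) -> GanTrainConfig:
    """Reference DCGAN settings: lr 2e-5, 2000 epochs."""
    cfg = GanTrainConfig(lr=2e-5, epochs=2000)
    return dataclasses.replace(cfg, **overrides)


@dataclasses.dataclass
class FadeInState:
    """Blend weight for the newest stage; ramps 0 -> 1 within a stage."""

    alpha: float = 1.0


def _stage_channels(base: int, stage: int, floor: int = 8) -> int:
    return max(floor, base >> stage)


# -- loss components ---------------------------------------------------------

def fade_in_blend(prev_upsampled, new_branch, alpha: float):
    """(1 - alpha) * prev + alpha * new, elementwise; works on arrays/tensors."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if isinstance(prev_upsampled, Tensor) or isinstance(new_branch, Tensor):
        a, b = T.astensor(prev_upsampled), T.astensor(new_branch)
        if a.shape != b.shape:
            raise ValueError("fade_in_blend requires equal shapes")
        return a * Tensor(1.0 - alpha) + b * Tensor(alpha)
    a, b = np.asarray(prev_upsampled), np.asarray(new_branch)
    if a.shape != b.shape:
        raise ValueError("fade_in_blend requires equal shapes")
    return (1.0 - alpha) * a + alpha * b


def gradient_penalty(
    critic,
    real_batch,
    fake_batch,
    gp_lambda: float = 10.0,
    *,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> Tensor:
    """WGAN-GP penalty: lambda * E[(||grad_xhat C(xhat)||_2 - 1)^2].

    xhat = eps*real + (1-eps)*fake with per-sample eps ~ U(0,1). Pass ``eps``
    for a deterministic evaluation; otherwise draws from ``rng``.
    """
    real = np.asarray(real_batch, dtype=np.float64)
    fake = np.asarray(fake_batch, dtype=np.float64)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    n = real.shape[0]
    if eps is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        eps = rng.uniform(size=(n,) + (1,) * (real.ndim - 1))
    xhat = Tensor(eps * real + (1.0 - eps) * fake, requires_grad=True)
    out = critic(xhat)
    (gx,) = grad(T.tsum(out), [xhat], create_graph=True)
    axes = tuple(range(1, real.ndim))
    norm = (T.tsum(gx * gx, axis=axes) + Tensor(1e-12)) ** 0.5
    return Tensor(float(gp_lambda)) * T.tmean((norm - Tensor(1.0)) ** 2)


def critic_loss(
    critic,
    real_batch,
    fake_batch,
    gp_lambda: float = 10.0,
    *,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> Tensor:
    """Wasserstein critic objective: mean C(fake) - mean C(real) + penalty."""
    loss = T.tmean(critic(T.astensor(fake_batch))) - T.tmean(
        critic(T.astensor(real_batch))
    )
    if gp_lambda > 0:
        loss = loss + gradient_penalty(
            critic, real_batch, fake_batch, gp_lambda, rng=rng, eps=eps
        )
    return loss


def generator_loss(critic, fake_batch) -> Tensor:
    """Generator objective: -mean C(fake)."""
    return -T.tmean(critic(T.astensor(fake_batch)))


# -- progressive architecture ------------------------------------------------

class PGGANGenerator(L.Module):
    """Grown generator: a 4x4 seed block plus two 3x3 convolutions per
    growth event, with per-stage toRGB adapters."""

    def __init__(self, schedule: StageSchedule, config: GanTrainConfig, rng):
        self.schedule = schedule
        self.config = config
        chans = [_stage_channels(config.base_channels, i) for i in range(schedule.n_stages)]
        self.channels = chans
        start = schedule.resolutions[0]
        self.start_res = start
        self.input_proj = L.Dense(config.latent_dim, chans[0] * start * start, rng=rng)
        act = lambda: L.LeakyReLU(0.2)
        norm = (lambda: L.PixelNorm()) if config.use_pixelnorm else (lambda: _Identity())
        self.blocks = [
            L.Sequential(
                L.Conv2d(chans[0], chans[0], 3, padding=1, rng=rng), act(), norm(),
                L.Conv2d(chans[0], chans[0], 3, padding=1, rng=rng), act(), norm(),
            )
        ]
        for i in range(1, schedule.n_stages):
            self.blocks.append(
                L.Sequential(
                    L.Upsample(2),
                    L.Conv2d(chans[i - 1], chans[i], 3, padding=1, rng=rng), act(), norm(),
                    L.Conv2d(chans[i], chans[i], 3, padding=1, rng=rng), act(), norm(),
                )
            )
        self.to_rgb = [L.Conv2d(c, 3, 1, rng=rng) for c in chans]
        self.upsample = L.Upsample(2)

    def forward(self, z: Tensor, stage: int | None = None, alpha: float = 1.0) -> Tensor:
        stage = self.schedule.n_stages - 1 if stage is None else stage
        n = z.shape[0]
        x = self.input_proj(z)
        x = T.leaky_relu(
            T.reshape(x, (n, self.channels[0], self.start_res, self.start_res)), 0.2
        )
        x = self.blocks[0](x)
        prev = None
        for i in range(1, stage + 1):
            prev = x
            x = self.blocks[i](x)
        out = self.to_rgb[stage](x)
        if stage > 0 and alpha < 1.0:
            low = self.to_rgb[stage - 1](prev)
            out = fade_in_blend(self.upsample(low), out, alpha)
        return out


class _Identity(L.Module):
    def forward(self, x):
        return x


class PGGANCritic(L.Module):
    """Mirror of the generator: per-stage fromRGB adapters, two 3x3
    convolutions per stage, and a final two-conv + fully-connected head."""

    def __init__(self, schedule: StageSchedule, config: GanTrainConfig, rng):
        self.schedule = schedule
        self.config = config
        chans = [_stage_channels(config.base_channels, i) for i in range(schedule.n_stages)]
        self.channels = chans
        act = lambda: L.LeakyReLU(0.2)
        self.from_rgb = [L.Conv2d(3, c, 1, rng=rng) for c in chans]
        self.blocks = []
        for i in range(1, schedule.n_stages):
            self.blocks.append(
                L.Sequential(
                    L.Conv2d(chans[i], chans[i], 3, padding=1, rng=rng), act(),
                    L.Conv2d(chans[i], chans[i - 1], 3, padding=1, rng=rng), act(),
                    L.AvgPool2d(2),
                )
            )
        head_in = chans[0] + (1 if config.use_minibatch_stddev else 0)
        start = schedule.resolutions[0]
        self.mbstd = L.MinibatchStdDev() if config.use_minibatch_stddev else None
        self.head_convs = L.Sequential(
            L.Conv2d(head_in, chans[0], 3, padding=1, rng=rng), act(),
            L.Conv2d(chans[0], chans[0], 3, padding=1, rng=rng), act(),
        )
        self.head_fc = L.Dense(chans[0] * start * start, 1, rng=rng)
        self.downsample = L.AvgPool2d(2)

    def forward(self, x: Tensor, stage: int | None = None, alpha: float = 1.0) -> Tensor:
        stage = self.schedule.n_stages - 1 if stage is None else stage
        h = T.leaky_relu(self.from_rgb[stage](x), 0.2)
        if stage > 0:
            h = self.blocks[stage - 1](h)
            if alpha < 1.0:
                low = T.leaky_relu(self.from_rgb[stage - 1](self.downsample(x)), 0.2)
                h = fade_in_blend(low, h, alpha)
            for i in range(stage - 1, 0, -1):
                h = self.blocks[i - 1](h)
        if self.mbstd is not None:
            h = self.mbstd(h)
        h = self.head_convs(h)
        n = h.shape[0]
        return self.head_fc(T.reshape(h, (n, int(np.prod(h.shape[1:])))))


@dataclasses.dataclass
class GeneratorState:
    """A trained (or initialised) generator plus everything needed to
    reproduce and continue: critic, schedule, config, training log."""

    generator: L.Module
    critic: L.Module
    schedule: StageSchedule
    config: GanTrainConfig
    kind: str = "pggan"
    log: list = dataclasses.field(default_factory=list)

    @property
    def resolution(self) -> int:
        return self.schedule.target_res


# -- data plumbing -----------------------------------------------------------

def images_to_training_array(images: np.ndarray) -> np.ndarray:
    """uint8 (N,H,W,3) -> float (N,3,H,W) in [-1, 1]."""
    x = np.asarray(images)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected (N, H, W, 3) images")
    x = x.astype(np.float64) / 255.0
    return np.transpose(x * 2.0 - 1.0, (0, 3, 1, 2))


def _downsample_to(x: np.ndarray, res: int) -> np.ndarray:
    n, c, h, w = x.shape
    f = h // res
    if f == 1:
        return x
    return x.reshape(n, c, res, f, res, f).mean(axis=(3, 5))


def training_array_to_images(x: np.ndarray) -> np.ndarray:
    """float (N,3,H,W) in [-1,1] -> uint8 (N,H,W,3)."""
    imgs = np.transpose((np.clip(x, -1, 1) + 1.0) / 2.0 * 255.0, (0, 2, 3, 1))
    return np.clip(np.rint(imgs), 0, 255).astype(np.uint8)


# -- training ----------------------------------------------------------------

def _stage_plan(config: GanTrainConfig, schedule: StageSchedule, n_images: int):
    """Split the total epoch budget evenly across stages; at least one
    optimisation step per stage."""
    per_stage_epochs = config.epochs / schedule.n_stages
    steps = max(1, int(np.ceil(per_stage_epochs * n_images / config.batch_size)))
    return [steps] * schedule.n_stages


def train_pggan(
    patch_images: np.ndarray,
    config: GanTrainConfig,
    schedule: StageSchedule | None = None,
) -> GeneratorState:
    """Train one progressive GAN on a single class of patches.

    ``patch_images``: uint8 (N, H, W, 3) with H = W = the schedule's target
    resolution. Returns the generator at target resolution with a per-step
    training log (stage, alpha, critic and generator losses).
    """
    config.validate()
    x_full = images_to_training_array(patch_images)
    n, _, h, w = x_full.shape
    if n == 0:
        raise ValueError("empty training set")
    if h != w:
        raise ValueError("training patches must be square")
    if schedule is None:
        schedule = build_stage_schedule(4, h)
    if schedule.target_res != h:
        raise ValueError(
            f"dataset resolution {h} does not match schedule target {schedule.target_res}"
        )

    rng = np.random.default_rng(config.seed)
    gen = PGGANGenerator(schedule, config, rng)
    crit = PGGANCritic(schedule, config, rng)
    opt_g = Adam(gen.parameters(), lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    opt_c = Adam(crit.parameters(), lr=config.lr, beta1=config.beta1, beta2=config.beta2)

    log: list[dict] = []
    plan = _stage_plan(config, schedule, n)
    for stage, steps in enumerate(plan):
        res = schedule.resolutions[stage]
        x_stage = _downsample_to(x_full, res)
        fade_steps = int(np.floor(config.fade_in_fraction * steps)) if stage > 0 else 0
        state = FadeInState(alpha=1.0)
        for step in range(steps):
            if fade_steps > 0:
                state.alpha = min(1.0, (step + 1) / fade_steps)
            alpha = state.alpha

            def critic_fn(t):
                return crit(t, stage=stage, alpha=alpha)

            idx = rng.integers(0, n, size=config.batch_size)
            real = x_stage[idx]
            z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
            with no_grad():
                fake = gen(z, stage=stage, alpha=alpha).data

            d_loss = critic_loss(
                critic_fn, real, fake, config.gp_lambda, rng=rng
            )
            opt_c.zero_grad()
            T.backward(d_loss, opt_c.params)
            opt_c.step()

            g_loss_val = np.nan
            if (step + 1) % config.n_critic == 0:
                z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
                fake_t = gen(z, stage=stage, alpha=alpha)
                g_loss = generator_loss(critic_fn, fake_t)
                opt_g.zero_grad()
                T.backward(g_loss, opt_g.params)
                opt_g.step()
                g_loss_val = g_loss.item()

            log.append(
                {
                    "stage": stage, "res": res, "step": step, "alpha": alpha,
                    "d_loss": d_loss.item(), "g_loss": g_loss_val,
                }
            )
    return GeneratorState(gen, crit, schedule, config, kind="pggan", log=log)


def sample_images(
    state: GeneratorState, n: int, seed: int, batch_size: int = 64
) -> np.ndarray:
    """Draw ``n`` images from the generator: uint8 (n, res, res, 3)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    outs = []
    done = 0
    while done < n:
        b = min(batch_size, n - done)
        z = Tensor(rng.standard_normal((b, state.config.latent_dim)))
        with no_grad():
            if state.kind == "pggan":
                x = state.generator(z).data
            else:
                x = state.generator(z).data
        outs.append(training_array_to_images(x))
        done += b
    return np.concatenate(outs, axis=0)


# -- DCGAN baseline ----------------------------------------------------------

class DCGANGenerator(L.Module):
    """Five convolutional layers and four upscaling layers, latent dim 128."""

    def __init__(self, target_res: int, config: GanTrainConfig, rng):
        if target_res % 16 != 0:
            raise InvalidConfigError("DCGAN target resolution must be divisible by 16")
        self.start = target_res // 16
        ch = config.base_channels
        self.channels = ch
        self.input_proj = L.Dense(config.latent_dim, ch * self.start * self.start, rng=rng)
        chans = [ch, max(8, ch // 2), max(8, ch // 4), max(8, ch // 8)]
        body = []
        cin = ch
        for c in chans[1:]:
            body += [L.Upsample(2), L.Conv2d(cin, c, 3, padding=1, rng=rng), L.LeakyReLU(0.2)]
            cin = c
        body += [L.Upsample(2), L.Conv2d(cin, cin, 3, padding=1, rng=rng), L.LeakyReLU(0.2)]
        self.body = L.Sequential(*body)
        self.to_rgb = L.Conv2d(cin, 3, 3, padding=1, rng=rng)

    def forward(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        x = T.leaky_relu(
            T.reshape(self.input_proj(z), (n, self.channels, self.start, self.start)), 0.2
        )
        return T.tanh(self.to_rgb(self.body(x)))


class DCGANDiscriminator(L.Module):
    """Six convolution layers followed by a single fully connected layer."""

    def __init__(self, target_res: int, config: GanTrainConfig, rng):
        ch = max(8, config.base_channels // 8)
        convs = [L.Conv2d(3, ch, 3, padding=1, rng=rng), L.LeakyReLU(0.2)]
        res = target_res
        cin = ch
        for _ in range(4):
            cout = min(config.base_channels, cin * 2)
            convs += [L.Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng), L.LeakyReLU(0.2)]
            cin = cout
            res //= 2
        convs += [L.Conv2d(cin, cin, 3, padding=1, rng=rng), L.LeakyReLU(0.2)]
        self.convs = L.Sequential(*convs)
        self.fc = L.Dense(cin * res * res, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.convs(x)
        return self.fc(T.reshape(h, (h.shape[0], int(np.prod(h.shape[1:])))))


def architecture_summary(module: L.Module) -> dict:
    """Counts of layer kinds, for structural audits."""
    counts = {"conv": 0, "fc": 0, "scaling": 0}
    for m in module.modules():
        if isinstance(m, L.Conv2d):
            counts["conv"] += 1
        elif isinstance(m, L.Dense):
            counts["fc"] += 1
        elif isinstance(m, L.Upsample):
            counts["scaling"] += 1
    return counts


def train_dcgan(patch_images: np.ndarray, config: GanTrainConfig) -> GeneratorState:
    """Non-progressive baseline trained with the standard (non-Wasserstein)
    adversarial logistic loss."""
    config.validate()
    x = images_to_training_array(patch_images)
    n, _, h, w = x.shape
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    gen = DCGANGenerator(h, config, rng)
    disc = DCGANDiscriminator(h, config, rng)
    opt_g = Adam(gen.parameters(), lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    opt_d = Adam(disc.parameters(), lr=config.lr, beta1=config.beta1, beta2=config.beta2)

    steps = max(1, int(np.ceil(config.epochs * n / config.batch_size)))
    log = []
    for step in range(steps):
        idx = rng.integers(0, n, size=config.batch_size)
        real = Tensor(x[idx])
        z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
        with no_grad():
            fake = Tensor(gen(z).data)
        # -log sigmoid(D(real)) - log(1 - sigmoid(D(fake)))
        d_loss = T.tmean(T.softplus(-disc(real))) + T.tmean(T.softplus(disc(fake)))
        opt_d.zero_grad()
        T.backward(d_loss, opt_d.params)
        opt_d.step()

        z = Tensor(rng.standard_normal((config.batch_size, config.latent_dim)))
        fake_t = gen(z)
        g_loss = T.tmean(T.softplus(-disc(fake_t)))  # non-saturating
        opt_g.zero_grad()
        T.backward(g_loss, opt_g.params)
        opt_g.step()
        log.append({"step": step, "d_loss": d_loss.item(), "g_loss": g_loss.item()})

    schedule = StageSchedule((h,))
    return GeneratorState(gen, disc, schedule, config, kind="dcgan", log=log)


# -- checkpointing -----------------------------------------------------------

def save_generator_state(state: GeneratorState, path: str | Path) -> None:
    """Single-file checkpoint: config + schedule + parameters."""
    path = Path(path)
    meta = {
        "kind": state.kind,
        "config": dataclasses.asdict(state.config),
        "resolutions": list(state.schedule.resolutions),
    }
    arrays = {f"gen_{k}": v for k, v in state.generator.state_arrays().items()}
    arrays |= {f"crit_{k}": v for k, v in state.critic.state_arrays().items()}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_generator_state(path: str | Path) -> GeneratorState:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = GanTrainConfig(**meta["config"])
        schedule = StageSchedule(tuple(meta["resolutions"]))
        rng = np.random.default_rng(0)
        if meta["kind"] == "pggan":
            gen = PGGANGenerator(schedule, config, rng)
            crit = PGGANCritic(schedule, config, rng)
        else:
            gen = DCGANGenerator(schedule.target_res, config, rng)
            crit = DCGANDiscriminator(schedule.target_res, config, rng)
        gen.load_state_arrays(
            {k[4:]: data[k] for k in data.files if k.startswith("gen_")}
        )
        crit.load_state_arrays(
            {k[5:]: data[k] for k in data.files if k.startswith("crit_")}
        )
    return GeneratorState(gen, crit, schedule, config, kind=meta["kind"])
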