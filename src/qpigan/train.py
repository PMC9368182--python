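"""Cycle-consistent adversarial training on unpaired intensity/phase data.

Implements the least-squares GAN objective with an L1 cycle-consistency
term weighted by λ (default 10):

    L = L_GAN + λ·(L_cycle_ABA + L_cycle_BAB)

Two generators (A→B intensity-to-phase, B→A phase-to-intensity) and two
PatchGAN discriminators are updated alternately with Adam.  The printed
adversarial objective mixes both players' terms in one expression; here it
is factorised in the standard least-squares form, discriminator
(D(real)−1)² + D(fake)² and generator (D(fake)−1)², which preserves the
overall loss structure while giving each player a minimisable objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rescale as _sk_rescale

from .autograd import Adam, Tensor, no_grad
from .models import (
    ContransGenerator,
    DiscriminatorConfig,
    GeneratorConfig,
    PatchDiscriminator,
)
from .optics import UnpairedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LossReport",
    "TrainResult",
    "adversarial_losses",
    "cycle_loss",
    "total_loss",
    "augment",
    "ReplayBuffer",
    "fit",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 2
    learning_rate: float = 2e-4
    crop_size: int | None = None
    seed: int = 0
    lambda_cyc: float = 10.0
    replay_buffer: int = 50
    lr_decay: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class LossReport:
    """Loss components of one step (or one epoch's mean).

    Invariant: ``total = loss_gan + lambda_cyc·(loss_cycle_aba + loss_cycle_bab)``.
    """

    loss_gan: float
    loss_cycle_aba: float
    loss_cycle_bab: float
    lambda_cyc: float = 10.0
    total: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total",
            self.loss_gan + self.lambda_cyc * (self.loss_cycle_aba + self.loss_cycle_bab))


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, False
    return Tensor(np.asarray(x, dtype=np.float32)), True


def adversarial_losses(d_real, d_fake):
    """Least-squares GAN losses from discriminator score maps.

    loss_d = mean((D(real)−1)²) + mean(D(fake)²);  loss_g = mean((D(fake)−1)²).
    Accepts numpy arrays (returns floats) or Tensors (stays on the graph).
    """
    real, np_in = _as_tensor(d_real)
    fake, _ = _as_tensor(d_fake)
    if not (np.all(np.isfinite(real.data)) and np.all(np.isfinite(fake.data))):
        raise ValueError("non-finite discriminator scores")
    loss_d = ((real - 1.0) ** 2).mean() + (fake ** 2).mean()
    loss_g = ((fake - 1.0) ** 2).mean()
    if np_in:
        return float(loss_d.numpy()), float(loss_g.numpy())
    return loss_d, loss_g


def cycle_loss(a, rec_a, b, rec_b):
    """Mean absolute (L1) reconstruction error per cycle direction."""
    at, np_in = _as_tensor(a)
    ra, _ = _as_tensor(rec_a)
    bt, _ = _as_tensor(b)
    rb, _ = _as_tensor(rec_b)
    if at.shape != ra.shape or bt.shape != rb.shape:
        raise ValueError("shape mismatch between images and reconstructions")
    loss_aba = (ra - at).abs().mean()
    loss_bab = (rb - bt).abs().mean()
    if np_in:
        return float(loss_aba.numpy()), float(loss_bab.numpy())
    return loss_aba, loss_bab


def total_loss(loss_gan: float, loss_cycle_aba: float, loss_cycle_bab: float,
               lambda_cyc: float = 10.0) -> LossReport:
    return LossReport(float(loss_gan), float(loss_cycle_aba), float(loss_cycle_bab),
                      float(lambda_cyc))


def augment(image: np.ndarray, crop_size: int, seed: int) -> np.ndarray:
    """Random crop, or random rescale (factor 0.8–1.2, interpolation drawn
    from nearest/bilinear/bicubic) followed by a crop, to ``crop_size``."""
    img = np.asarray(image, dtype=np.float32)
    if crop_size > min(img.shape):
        raise ValueError(f"crop_size {crop_size} exceeds image dims {img.shape}")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        factor = rng.uniform(0.8, 1.2)
        order = int(rng.choice([0, 1, 3]))
        scaled = _sk_rescale(img, factor, order=order, anti_aliasing=order > 0,
                             preserve_range=True).astype(np.float32)
        if min(scaled.shape) >= crop_size:
            img = scaled
    dy = int(rng.integers(0, img.shape[0] - crop_size + 1))
    dx = int(rng.integers(0, img.shape[1] - crop_size + 1))
    return img[dy:dy + crop_size, dx:dx + crop_size].copy()


class ReplayBuffer:
    """Pool of historical generated images fed to the discriminators, the
    usual stabilisation trick for cycle-consistent GANs.  With probability
    1/2 a query returns (and replaces) a stored past fake instead of the
    current one."""

    def __init__(self, capacity: int, rng: np.random.Generator):
        self.capacity = capacity
        self.rng = rng
        self.items: list[np.ndarray] = []

    def query(self, fake: np.ndarray) -> np.ndarray:
        if self.capacity <= 0:
            return fake
        if len(self.items) < self.capacity:
            self.items.append(fake.copy())
            return fake
        if self.rng.random() < 0.5:
            i = int(self.rng.integers(len(self.items)))
            out = self.items[i].copy()
            self.items[i] = fake.copy()
            return out
        return fake


def _minmax(images) -> tuple[float, float]:
    lo = min(float(np.min(im)) for im in images)
    hi = max(float(np.max(im)) for im in images)
    if hi <= lo:
        hi = lo + 1.0
    return lo, hi


def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (2.0 * (x - lo) / (hi - lo) - 1.0).astype(np.float32)


def _unscale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return ((x + 1.0) * 0.5 * (hi - lo) + lo).astype(np.float64)


@dataclass
class TrainResult:
    g_ab: ContransGenerator
    g_ba: ContransGenerator
    d_a: PatchDiscriminator
    d_b: PatchDiscriminator
    history: list[LossReport]
    history_disc: list[float]
    scale_a: tuple[float, float]
    scale_b: tuple[float, float]

    def translate_a_to_b(self, image: np.ndarray) -> np.ndarray:
        """Map a raw intensity image to a phase map in physical units."""
        x = _scale(np.asarray(image, dtype=np.float64), *self.scale_a)
        with no_grad():
            y = self.g_ab(Tensor(x[None, None])).numpy()[0, 0]
        return _unscale(y, *self.scale_b)


def fit(train: UnpairedDataset, config: TrainConfig,
        gen_config: GeneratorConfig, disc_config: DiscriminatorConfig) -> TrainResult:
    """Train the unpaired intensity→phase translation pair.

    Per step: sample unpaired batches a, b; form F_B = G_AB(a),
    F_A = G_BA(b) and the reconstructions RE_A = G_BA(F_B),
    RE_B = G_AB(F_A); update the generators on the adversarial + λ·cycle
    objective and the discriminators on the least-squares real/fake split
    (with a replay buffer of past fakes).  Returns per-epoch mean loss
    reports; fully deterministic given the seeds.
    """
    if not train.set_a or not train.set_b:
        raise ValueError("training dataset is empty")
    imgs_a = [np.asarray(im.values, dtype=np.float64) for im in train.set_a]
    imgs_b = [np.asarray(pm.values, dtype=np.float64) for pm in train.set_b]
    scale_a = _minmax(imgs_a)
    scale_b = _minmax(imgs_b)
    imgs_a = [_scale(im, *scale_a) for im in imgs_a]
    imgs_b = [_scale(im, *scale_b) for im in imgs_b]

    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_sample = np.random.default_rng(ss[0])
    rng_buf = np.random.default_rng(ss[1])
    rng_aug = np.random.default_rng(ss[2])

    import dataclasses as _dc

    g_ab = ContransGenerator(gen_config)
    g_ba = ContransGenerator(_dc.replace(gen_config, seed=gen_config.seed + 1))
    d_a = PatchDiscriminator(_dc.replace(disc_config, seed=disc_config.seed + 2))
    d_b = PatchDiscriminator(_dc.replace(disc_config, seed=disc_config.seed + 3))

    opt_g = Adam(g_ab.parameters() + g_ba.parameters(), lr=config.learning_rate)
    opt_d = Adam(d_a.parameters() + d_b.parameters(), lr=config.learning_rate)
    buf_a = ReplayBuffer(config.replay_buffer, rng_buf)
    buf_b = ReplayBuffer(config.replay_buffer, rng_buf)

    n_steps = max(1, min(len(imgs_a), len(imgs_b)) // config.batch_size)
    history: list[LossReport] = []
    history_disc: list[float] = []

    for epoch in range(config.epochs):
        if config.lr_decay and epoch >= config.epochs // 2:
            frac = (epoch - config.epochs // 2) / max(1, config.epochs - config.epochs // 2)
            lr = config.learning_rate * (1.0 - frac)
            opt_g.lr = opt_d.lr = max(lr, 1e-6)
        ep_gan = ep_aba = ep_bab = ep_d = 0.0
        for step in range(n_steps):
            ia = rng_sample.choice(len(imgs_a), size=config.batch_size)
            ib = rng_sample.choice(len(imgs_b), size=config.batch_size)
            batch_a = [imgs_a[i] for i in ia]
            batch_b = [imgs_b[i] for i in ib]
            if config.crop_size is not None:
                batch_a = [augment(im, config.crop_size, int(rng_aug.integers(2 ** 31)))
                           for im in batch_a]
                batch_b = [augment(im, config.crop_size, int(rng_aug.integers(2 ** 31)))
                           for im in batch_b]
            a = Tensor(np.stack(batch_a)[:, None])
            b = Tensor(np.stack(batch_b)[:, None])

            # generator update
            fb = g_ab(a)
            fa = g_ba(b)
            rec_a = g_ba(fb)
            rec_b = g_ab(fa)
            _, loss_g_b = adversarial_losses(d_b(b), d_b(fb))
            _, loss_g_a = adversarial_losses(d_a(a), d_a(fa))
            loss_gan_g = loss_g_a + loss_g_b
            l_aba, l_bab = cycle_loss(a, rec_a, b, rec_b)
            g_total = loss_gan_g + config.lambda_cyc * (l_aba + l_bab)
            if not np.isfinite(g_total.numpy()):
                raise RuntimeError(f"training diverged at epoch {epoch}, step {step}")
            opt_g.zero_grad()
            g_total.backward()
            opt_g.step()

            # discriminator update on detached (and replayed) fakes
            fa_d = Tensor(buf_a.query(fa.numpy()))
            fb_d = Tensor(buf_b.query(fb.numpy()))
            loss_d_a, _ = adversarial_losses(d_a(a), d_a(fa_d))
            loss_d_b, _ = adversarial_losses(d_b(b), d_b(fb_d))
            d_total = (loss_d_a + loss_d_b) * 0.5
            if not np.isfinite(d_total.numpy()):
                raise RuntimeError(f"training diverged at epoch {epoch}, step {step}")
            opt_d.zero_grad()
            d_total.backward()
            opt_d.step()

            ep_gan += float(loss_gan_g.numpy())
            ep_aba += float(l_aba.numpy())
            ep_bab += float(l_bab.numpy())
            ep_d += float(d_total.numpy())

        report = total_loss(ep_gan / n_steps, ep_aba / n_steps, ep_bab / n_steps,
                            config.lambda_cyc)
        history.append(report)
        history_disc.append(ep_d / n_steps)
        logger.info("epoch %d: total %.4f (gan %.4f, cycle %.4f/%.4f, d %.4f)",
                    epoch, report.total, report.loss_gan,
                    report.loss_cycle_aba, report.loss_cycle_bab, ep_d / n_steps)

    return TrainResult(g_ab, g_ba, d_a, d_b, history, history_disc, scale_a, scale_b)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, result: TrainResult, gen_config: GeneratorConfig,
                    disc_config: DiscriminatorConfig) -> None:
    """Single-file archive: networks' weights plus a JSON header carrying the
    full architecture configuration and the physical scaling, so inference
    needs nothing but the checkpoint."""
    header = {
        "format": "qpigan-checkpoint-v1",
        "generator": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in gen_config.__dict__.items()},
        "discriminator": dict(disc_config.__dict__),
        "scale_a": list(result.scale_a),
        "scale_b": list(result.scale_b),
    }
    arrays: dict[str, np.ndarray] = {}
    for tag, module in (("g_ab", result.g_ab), ("g_ba", result.g_ba),
                        ("d_a", result.d_a), ("d_b", result.d_b)):
        for k, v in module.state_dict().items():
            arrays[f"{tag}/{k}"] = v
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainResult:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != "qpigan-checkpoint-v1":
            raise ValueError("not a recognised checkpoint file")
        gcfg_d = dict(header["generator"])
        for k in ("depths", "num_heads"):
            gcfg_d[k] = tuple(gcfg_d[k])
        gen_config = GeneratorConfig(**gcfg_d)
        disc_config = DiscriminatorConfig(**header["discriminator"])
        modules = {
            "g_ab": ContransGenerator(gen_config),
            "g_ba": ContransGenerator(gen_config),
            "d_a": PatchDiscriminator(disc_config),
            "d_b": PatchDiscriminator(disc_config),
        }
        for tag, module in modules.items():
            state = {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(tag + "/")}
            module.load_state_dict(state)
    return TrainResult(modules["g_ab"], modules["g_ba"], modules["d_a"], modules["d_b"],
                       history=[], history_disc=[],
                       scale_a=tuple(header["scale_a"]), scale_b=tuple(header["scale_b"]))
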