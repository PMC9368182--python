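"""Generator and discriminator architectures.

The generator ("Contrans") pairs a windowed-attention (Swin) branch, which
captures global context through hierarchical window attention and patch
merging, with a convolutional encoder–decoder branch that keeps local
detail.  Swin stage features are reshaped to spatial maps, magnified four
times by nearest-neighbour upsampling, and concatenated into the CNN
decoder at the level whose pixel pitch they then match.

The discriminator is a PatchGAN: a stride-2 conv stack emitting one real
score per overlapping receptive patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .nn import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LayerNorm,
    Module,
    PatchMerging,
    SwinBlock,
)

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "ContransGenerator",
           "PatchDiscriminator", "contrans_forward", "patchgan_forward",
           "dry_run_shapes"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture plan for the hybrid generator.

    The printed description of the network fixes the 4-pixel initial patch,
    the 7-patch window and the 224 → 7×7 attention endpoint; stage depths,
    head counts and widths are configuration defaults (Swin-T-like, width
    scaled for desk-scale training).
    """

    img_size: int = 224
    in_channels: int = 1
    patch_size: int = 4
    window: int = 7
    depths: tuple[int, ...] = (2, 2, 2, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    embed_dim: int = 96
    cnn_channels: int = 32
    width_scale: float = 0.5
    mlp_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.num_heads):
            raise ValueError("depths and num_heads must have equal length")
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be >= 1")
        self.validate_size(self.img_size)
        for i, h in enumerate(self.num_heads):
            if self.stage_dim(i) % h:
                raise ValueError(
                    f"stage {i}: dim {self.stage_dim(i)} not divisible by {h} heads")

    @property
    def base_dim(self) -> int:
        return max(1, int(round(self.embed_dim * self.width_scale)))

    def stage_dim(self, stage: int) -> int:
        return self.base_dim * 2 ** stage

    @property
    def base_cnn(self) -> int:
        return max(1, int(round(self.cnn_channels * self.width_scale)))

    @property
    def divisor(self) -> int:
        """Input sizes must be divisible by patch·window·2^(stages−1) and 8."""
        return int(np.lcm(self.patch_size * self.window * 2 ** (len(self.depths) - 1), 8))

    def validate_size(self, size: int) -> None:
        if size % self.divisor:
            raise ValueError(
                f"input size {size} must be divisible by {self.divisor} "
                f"(patch {self.patch_size} x window {self.window} x "
                f"2^{len(self.depths) - 1} merges, and 8 for the CNN branch)")


@dataclass(frozen=True)
class DiscriminatorConfig:
    """PatchGAN plan: one unnormalised stride-2 conv, then ``n_layers``
    repeats of conv + instance norm + LeakyReLU (the first ``n_layers − 1``
    at stride 2, the last at stride 1), then the 1-channel score conv.
    The default ``n_layers=3`` gives the classic 70×70 receptive field and
    a 30×30 score map on a 256×256 input."""

    in_channels: int = 1
    base_channels: int = 64
    n_layers: int = 3
    width_scale: float = 1.0
    seed: int = 0

    @property
    def base(self) -> int:
        return max(1, int(round(self.base_channels * self.width_scale)))

    @property
    def strides(self) -> tuple[int, ...]:
        return (2,) + (2,) * (self.n_layers - 1) + (1, 1)

    @property
    def receptive_field(self) -> int:
        rf = 1
        for s in reversed(self.strides):
            rf = (rf - 1) * s + 4
        return rf


class _SwinStage(Module):
    def __init__(self, dim: int, depth: int, heads: int, window: int,
                 rng: np.random.Generator, mlp_ratio: float, downsample: bool):
        self.blocks = [
            SwinBlock(dim, heads, window, shift=0 if i % 2 == 0 else window // 2,
                      rng=rng, mlp_ratio=mlp_ratio)
            for i in range(depth)
        ]
        self.merge = PatchMerging(dim, rng) if downsample else None

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        for blk in self.blocks:
            x = blk(x)
        out = x
        if self.merge is not None:
            x = self.merge(x)
        return out, x


class ContransGenerator(Module):
    """Hybrid CNN + windowed-attention generator, single-channel in/out."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_cnn
        d = config.base_dim
        win = config.window

        # Swin branch: 4x4 patch embedding then hierarchical stages.
        self.patch_embed = Conv2d(config.in_channels, d, config.patch_size, rng,
                                  stride=config.patch_size)
        self.embed_norm = LayerNorm(d)
        n_stages = len(config.depths)
        self.stages = [
            _SwinStage(config.stage_dim(i), config.depths[i], config.num_heads[i],
                       win, rng, config.mlp_ratio, downsample=i < n_stages - 1)
            for i in range(n_stages)
        ]

        # CNN branch: 3-level stride-2 encoder and transposed-conv decoder.
        self.enc1 = Conv2d(config.in_channels, c, 4, rng, stride=2, padding=1)
        self.enc2 = Conv2d(c, 2 * c, 4, rng, stride=2, padding=1)
        self.enc3 = Conv2d(2 * c, 4 * c, 4, rng, stride=2, padding=1)

        # Fusion channel bookkeeping: swin stage i has dim d·2^i at pitch
        # patch·2^i; after x4 upsampling it lands at pitch patch·2^i/4.
        swin_dims = {config.patch_size * 2 ** i // 4: config.stage_dim(i)
                     for i in range(n_stages)}
        # bottleneck at pitch 8 (c4 channels) may receive a swin feature
        self.bottleneck = Conv2d(4 * c + swin_dims.get(8, 0), 4 * c, 3, rng, padding=1)
        self._swin_at = swin_dims

        self.dec3 = ConvTranspose2d(4 * c, 2 * c, 4, rng, stride=2, padding=1)
        self.fuse3 = Conv2d(2 * c + 2 * c + swin_dims.get(4, 0), 2 * c, 3, rng, padding=1)
        self.dec2 = ConvTranspose2d(2 * c, c, 4, rng, stride=2, padding=1)
        self.fuse2 = Conv2d(c + c + swin_dims.get(2, 0), c, 3, rng, padding=1)
        self.dec1 = ConvTranspose2d(c, c, 4, rng, stride=2, padding=1)
        self.fuse1 = Conv2d(c + swin_dims.get(1, 0), c, 3, rng, padding=1)
        self.head = Conv2d(c, config.in_channels, 3, rng, padding=1)
        self.norm = InstanceNorm2d()

    # -- swin branch -------------------------------------------------------

    def _swin_features(self, x: Tensor) -> dict[int, Tensor]:
        """Map pitch-after-x4-upsample → spatial feature map (B, C, h, w)."""
        cfg = self.config
        t = self.patch_embed(x)  # (B, d, H/4, W/4)
        t = t.transpose(0, 2, 3, 1)
        t = self.embed_norm(t)
        feats: dict[int, Tensor] = {}
        for i, stage in enumerate(self.stages):
            out, t = stage(t)
            pitch_here = cfg.patch_size * 2 ** i
            feats[pitch_here // 4] = out.transpose(0, 3, 1, 2).upsample_nearest(4)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError("expected input of shape (B, C, H, W)")
        if x.shape[2] != x.shape[3]:
            raise ValueError("expected a square input")
        cfg.validate_size(x.shape[2])

        swin = self._swin_features(x)

        e1 = self.norm(self.enc1(x)).leaky_relu()        # pitch 2
        e2 = self.norm(self.enc2(e1)).leaky_relu()       # pitch 4
        e3 = self.norm(self.enc3(e2)).leaky_relu()       # pitch 8

        b = e3 if 8 not in swin else concat([e3, swin[8]], axis=1)
        b = self.norm(self.bottleneck(b)).leaky_relu()

        d3 = self.dec3(b)                                 # pitch 4
        d3 = concat([d3, e2] + ([swin[4]] if 4 in swin else []), axis=1)
        d3 = self.norm(self.fuse3(d3)).leaky_relu()
        d2 = self.dec2(d3)                                # pitch 2
        d2 = concat([d2, e1] + ([swin[2]] if 2 in swin else []), axis=1)
        d2 = self.norm(self.fuse2(d2)).leaky_relu()
        d1 = self.dec1(d2)                                # pitch 1
        if 1 in swin:
            d1 = concat([d1, swin[1]], axis=1)
        d1 = self.norm(self.fuse1(d1)).leaky_relu()
        return self.head(d1)


class PatchDiscriminator(Module):
    """PatchGAN scoring overlapping receptive patches of the input."""

    def __init__(self, config: DiscriminatorConfig | None = None):
        config = config or DiscriminatorConfig()
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base
        chans = [config.in_channels] + [min(8, 2 ** i) * b for i in range(config.n_layers + 1)]
        self.convs = [
            Conv2d(chans[i], chans[i + 1], 4, rng, stride=s, padding=1)
            for i, s in enumerate(config.strides[:-1])
        ]
        self.score = Conv2d(chans[-1], 1, 4, rng, stride=1, padding=1)
        self.norm = InstanceNorm2d()

    @property
    def min_input(self) -> int:
        return self.config.receptive_field

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("expected input of shape (B, C, H, W)")
        if min(x.shape[2], x.shape[3]) < self.min_input:
            raise ValueError(
                f"input must be at least {self.min_input} pixels per side "
                f"(the discriminator's receptive field)")
        y = self.convs[0](x).leaky_relu()  # first stage carries no normalisation
        for conv in self.convs[1:]:
            y = self.norm(conv(y)).leaky_relu()
        return self.score(y)


# --------------------------------------------------------------------------
# functional surfaces
# --------------------------------------------------------------------------

def contrans_forward(image: np.ndarray, model: ContransGenerator) -> np.ndarray:
    """Run a single H×W (or H×W×1) image through the generator."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 1:
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    from .autograd import no_grad
    with no_grad():
        out = model(Tensor(img[None, None]))
    return out.numpy()[0, 0]


def patchgan_forward(image: np.ndarray, model: PatchDiscriminator) -> np.ndarray:
    """Score map of overlapping patches for a single-channel image."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[-1] == 1:
        img = img[..., 0]
    from .autograd import no_grad
    with no_grad():
        out = model(Tensor(img[None, None]))
    return out.numpy()[0, 0]


def dry_run_shapes(config: GeneratorConfig) -> dict[str, tuple[int, ...]]:
    """Walk the configured stage plan and assert every shape contract.

    Returns the token-grid shape per Swin stage; raises if any stage is
    incompatible with the window size or merging parity.
    """
    n = config.img_size // config.patch_size
    shapes: dict[str, tuple[int, ...]] = {}
    for i in range(len(config.depths)):
        if n % config.window:
            raise ValueError(f"stage {i}: token grid {n} not divisible by window")
        shapes[f"stage{i}"] = (n, n, config.stage_dim(i))
        if i < len(config.depths) - 1:
            if n % 2:
                raise ValueError(f"stage {i}: odd token grid {n} cannot merge")
            n //= 2
    return shapes
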