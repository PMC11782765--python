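"""DCGAN generator/discriminator pair for class balancing.

The generator projects a latent vector onto a (size/16, size/16, 512)
tensor and upsamples through four transposed-convolution stages
(channels 256 -> 128 -> 64 -> 32, each LeakyReLU + batch norm), ending
in a 3-channel tanh head. The discriminator is four stride-2
convolution blocks (LeakyReLU + dropout) with a sigmoid real/fake head.

Training follows the adversarial value function
V(R, C) = E[log R(x)] + E[log(1 - R(C(z)))]; the discriminator ascends
it while the generator descends the non-saturating surrogate
(maximize log R(C(z))), the standard stable reformulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.losses import binary_crossentropy
from .nn.optim import Adam
from .nn.tensor import Tensor

# Per-class epoch counts used for the published training runs.
PAPER_EPOCHS = {"DME": 400, "DRUSEN": 250}
GAN_TRAINING_POOL = 2000  # real images per minority class fed to the GAN


class GanError(ValueError):
    pass


@dataclass(frozen=True)
class GanConfig:
    noise_dim: int = 100
    image_size: int = 224
    learning_rate: float = 0.0008
    batch_size: int = 128
    epochs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise GanError("noise_dim must be >= 1")
        if self.learning_rate <= 0:
            raise GanError("learning_rate must be positive")
        if self.epochs < 1:
            raise GanError("epochs must be >= 1")
        if self.image_size < 16 or self.image_size % 16 != 0:
            raise GanError("image_size must be a positive multiple of 16")


GENERATOR_WIDTHS = (256, 128, 64, 32)
DISCRIMINATOR_WIDTHS = (32, 64, 128, 256)


class Generator(nn.Module):
    """noise (N, noise_dim) -> images (N, 3, size, size) in (-1, 1)."""

    def __init__(self, cfg: GanConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.base = cfg.image_size // 16
        self.project = nn.Dense(rng, cfg.noise_dim, self.base * self.base * 512)
        stages = []
        c_in = 512
        for c_out in GENERATOR_WIDTHS:
            stages.append(nn.ConvTranspose2d(rng, c_in, c_out, kernel=4,
                                             stride=2, padding=1))
            stages.append(nn.BatchNorm2d(c_out))
            c_in = c_out
        self.stages = nn.Sequential(*stages)
        self.head = nn.Conv2d(rng, c_in, 3, 3, stride=1, padding="same")

    def forward(self, z) -> Tensor:
        if not isinstance(z, Tensor):
            z = Tensor(z)
        x = self.project(z).reshape(z.shape[0], 512, self.base, self.base)
        x = x.leaky_relu(0.2)
        for i in range(0, len(self.stages.mods), 2):
            x = self.stages.mods[i](x).leaky_relu(0.2)
            x = self.stages.mods[i + 1](x)
        return self.head(x).tanh()


class Discriminator(nn.Module):
    """images (N, 3, size, size) -> real probability in (0, 1)."""

    def __init__(self, cfg: GanConfig, dropout: float = 0.3):
        super().__init__()
        rng = np.random.default_rng(cfg.seed + 1)
        self.cfg = cfg
        blocks = []
        c_in = 3
        for c_out in DISCRIMINATOR_WIDTHS:
            blocks.append(nn.Conv2d(rng, c_in, c_out, 4, stride=2, padding=1))
            blocks.append(nn.Dropout(rng, dropout))
            c_in = c_out
        self.blocks = nn.Sequential(*blocks)
        feat = cfg.image_size // 16
        self.head = nn.Dense(rng, c_in * feat * feat, 1)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[2] != self.cfg.image_size or x.shape[1] != 3:
            raise GanError(
                f"expected (N, 3, {self.cfg.image_size}, {self.cfg.image_size}) "
                f"input, got {x.shape}")
        for i in range(0, len(self.blocks.mods), 2):
            x = self.blocks.mods[i](x).leaky_relu(0.2)
            x = self.blocks.mods[i + 1](x)
        n, c, h, w = x.shape
        flat = x.reshape(n, c * h * w)
        return F.sigmoid(self.head(flat))


def build_generator(cfg: GanConfig = GanConfig()) -> Generator:
    return Generator(cfg)


def build_discriminator(cfg: GanConfig = GanConfig()) -> Discriminator:
    return Discriminator(cfg)


def images_to_tanh_range(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W) or (N, H, W, 3) -> float32 (N, 3, H, W) in [-1, 1]."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = np.repeat(x[:, None], 3, axis=1)
    elif x.ndim == 4:
        x = x.transpose(0, 3, 1, 2)
    else:
        raise GanError("expected (N, H, W) or (N, H, W, 3) images")
    return x / 127.5 - 1.0


def train_dcgan(images: np.ndarray, cfg: GanConfig,
                steps: int | None = None) -> tuple[Generator, dict]:
    """Adversarial training on one class of images.

    ``images``: uint8 array, already at ``cfg.image_size``. Returns the
    trained generator and a history dict with per-step ``d_loss``,
    ``g_loss`` and the adversarial value ``v`` (the logged objective),
    plus the trained discriminator under ``"discriminator"``.
    """
    x = images_to_tanh_range(images)
    n = x.shape[0]
    if n < cfg.batch_size:
        raise GanError(f"need at least one batch ({cfg.batch_size}) of images, "
                       f"got {n}")
    if x.shape[2] != cfg.image_size:
        raise GanError(f"images are {x.shape[2]}px but config expects "
                       f"{cfg.image_size}px; resize first")
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg)
    disc = Discriminator(cfg)
    opt_g = Adam(gen.parameters(), lr=cfg.learning_rate, beta1=0.5)
    opt_d = Adam(disc.parameters(), lr=cfg.learning_rate, beta1=0.5)
    if steps is None:
        steps = cfg.epochs * max(n // cfg.batch_size, 1)
    history = {"d_loss": [], "g_loss": [], "v": []}
    for _ in range(steps):
        idx = rng.choice(n, size=cfg.batch_size, replace=False)
        z = rng.standard_normal((cfg.batch_size, cfg.noise_dim)).astype(np.float32)
        d_loss, p_real = discriminator_step(gen, disc, opt_d, x[idx], z)
        z = rng.standard_normal((cfg.batch_size, cfg.noise_dim)).astype(np.float32)
        g_loss, p_fake = generator_step(gen, disc, opt_g, z)
        # logged value of the minimax objective
        eps = 1e-7
        v = float(np.mean(np.log(p_real + eps)) +
                  np.mean(np.log(1.0 - p_fake + eps)))
        history["d_loss"].append(d_loss)
        history["g_loss"].append(g_loss)
        history["v"].append(v)
    history["discriminator"] = disc
    return gen, history


def discriminator_step(gen: Generator, disc: Discriminator, opt_d,
                       real_batch: np.ndarray, z: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """One ascent step on log R(x) + log(1 - R(C(z))).

    Generator samples are detached, so the generator's weights (and
    gradients) are untouched.
    """
    b = len(z)
    fake = gen(z).detach()
    p_real = disc(real_batch)
    p_fake = disc(fake)
    d_loss = binary_crossentropy(p_real, np.ones((b, 1), dtype=np.float32)) + \
        binary_crossentropy(p_fake, np.zeros((b, 1), dtype=np.float32))
    opt_d.zero_grad()
    d_loss.backward()
    opt_d.step()
    return float(d_loss.data), p_real.data


def generator_step(gen: Generator, disc: Discriminator, opt_g,
                   z: np.ndarray) -> tuple[float, np.ndarray]:
    """One non-saturating generator step (maximize log R(C(z))).

    Gradients flow through the discriminator but only the generator's
    optimizer runs, so the discriminator's weights are conserved.
    """
    b = len(z)
    p_fake = disc(gen(z))
    g_loss = binary_crossentropy(p_fake, np.ones((b, 1), dtype=np.float32))
    opt_g.zero_grad()
    disc.zero_grad()
    g_loss.backward()
    opt_g.step()
    return float(g_loss.data), p_fake.data


def synthesize(generator: Generator, n: int, seed: int,
               batch_size: int = 32) -> np.ndarray:
    """Sample ``n`` images as uint8 (n, size, size, 3)."""
    if n <= 0:
        raise GanError("n must be positive")
    rng = np.random.default_rng(seed)
    was_training = generator.training
    generator.eval()
    outs = []
    for i in range(0, n, batch_size):
        b = min(batch_size, n - i)
        z = rng.standard_normal((b, generator.cfg.noise_dim)).astype(np.float32)
        img = generator(z).data  # (b, 3, H, W) in (-1, 1)
        img = np.rint((img.transpose(0, 2, 3, 1) + 1.0) * 127.5)
        outs.append(np.clip(img, 0, 255).astype(np.uint8))
    if was_training:
        generator.train()
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Augmentation accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassPlan:
    label: str
    original_count: int
    gan_training_count: int
    generated_count: int

    @property
    def total_count(self) -> int:
        return self.original_count + self.generated_count


@dataclass(frozen=True)
class AugmentationPlan:
    classes: tuple[ClassPlan, ...]

    @property
    def original_total(self) -> int:
        return sum(c.original_count for c in self.classes)

    @property
    def generated_total(self) -> int:
        return sum(c.generated_count for c in self.classes)

    @property
    def grand_total(self) -> int:
        return sum(c.total_count for c in self.classes)

    def totals_by_class(self) -> dict[str, int]:
        return {c.label: c.total_count for c in self.classes}

    def to_records(self) -> list[dict]:
        return [{"label": c.label, "original": c.original_count,
                 "gan_training": c.gan_training_count,
                 "generated": c.generated_count, "total": c.total_count}
                for c in self.classes]


def plan_augmentation(original_counts: dict[str, int],
                      generated_counts: dict[str, int],
                      gan_training_counts: dict[str, int] | None = None
                      ) -> AugmentationPlan:
    """Per-class original/generated/total accounting."""
    gan_training_counts = gan_training_counts or {}
    classes = []
    for label in original_counts:
        orig = int(original_counts[label])
        gen = int(generated_counts.get(label, 0))
        pool = int(gan_training_counts.get(
            label, GAN_TRAINING_POOL if gen > 0 else 0))
        if orig < 0 or gen < 0 or pool < 0:
            raise GanError("counts must be non-negative")
        if pool > orig:
            raise GanError(f"GAN training pool for {label} exceeds the "
                           f"original count ({pool} > {orig})")
        classes.append(ClassPlan(label, orig, pool, gen))
    return AugmentationPlan(tuple(classes))
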