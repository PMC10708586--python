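"""Adversarial generator/discriminator mapping EEG features to saliency maps.

The generator expands the classifier's feature vector through two dense
layers into a coarse spatial grid and upsamples it with four transposed
convolutions plus a final 2x2 valid convolution that trims the grid to the
canonical odd image side (50->100->300->300->300->299 in the ``paper``
profile).  The discriminator is three stride-2 same-padded convolutions
with dropout, flattened into a single sigmoid unit.  Training alternates
one discriminator and one generator step per batch under binary
cross-entropy (non-saturating generator loss) with Adam at lr 1e-4.

Bias conventions follow the printed parameter counts where those are
internally consistent: dense and transposed-conv layers are bias-free, the
final generator convolution and the discriminator head carry a bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .metrics import SSIMParams, cc, ssim
from .synthetic import SaliencyMap


@dataclass
class GeneratorSpec:
    """Feature-vector -> saliency-image generator architecture."""

    input_dim: int = 2500
    dense_sizes: tuple = (100, 20000)
    reshape: tuple = (8, 50, 50)  # channels, height, width
    transposed_channels: int = 6
    transposed_kernel: int = 4
    transposed_strides: tuple = ((2, 2), (3, 3), (1, 1), (1, 1))
    final_kernel: int = 2
    activation_slope: float = 0.1
    profile: str = "paper"

    def __post_init__(self):
        c, h, w = self.reshape
        if c * h * w != self.dense_sizes[1]:
            raise ValueError("reshape size must equal the second dense width")
        side = h
        for (sh, sw) in self.transposed_strides:
            if sh != sw:
                raise ValueError("square strides required")
            side *= sh
        self.output_side = side - self.final_kernel + 1

    @classmethod
    def desk(cls, input_dim: int = 64) -> "GeneratorSpec":
        # 8 -> 16 -> 64 -> 64 -> 64 -> 63: same stage structure, desk scale
        return cls(
            input_dim=input_dim,
            dense_sizes=(32, 512),
            reshape=(8, 8, 8),
            transposed_channels=4,
            transposed_strides=((2, 2), (4, 4), (1, 1), (1, 1)),
            profile="desk",
        )


@dataclass
class DiscriminatorSpec:
    """Saliency-image -> real/fake probability discriminator architecture."""

    input_side: int = 299
    conv_channels: int = 2
    conv_kernel: int = 4
    n_stages: int = 3
    dropout_rate: float = 0.2
    activation_slope: float = 0.1
    profile: str = "paper"

    def __post_init__(self):
        side = self.input_side
        self.stage_sides = []
        for _ in range(self.n_stages):
            side = -(-side // 2)  # stride-2 'same' convolution
            self.stage_sides.append(side)
        self.flatten_length = side * side * self.conv_channels

    @classmethod
    def desk(cls, input_side: int = 63) -> "DiscriminatorSpec":
        return cls(input_side=input_side, profile="desk")


@dataclass
class GanPair:
    """A generator/discriminator pair with the specs they were built from."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    gen_spec: object
    disc_spec: object
    seed: int = 42


def build_generator(spec: GeneratorSpec, seed: int = 42) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Dense(spec.dense_sizes[0], bias=False),
        nn.Dense(spec.dense_sizes[1], bias=False),
        nn.LeakyReLU(spec.activation_slope),
        nn.Reshape(spec.reshape),
    ]
    for stride in spec.transposed_strides:
        layers += [
            nn.ConvTranspose2d(
                spec.transposed_channels, spec.transposed_kernel, stride=stride,
                bias=False,
            ),
            nn.LeakyReLU(spec.activation_slope),
        ]
    layers += [
        nn.Conv2d(1, spec.final_kernel, stride=1, padding="valid", bias=True),
        nn.LeakyReLU(spec.activation_slope),
    ]
    return nn.Sequential(layers, input_shape=(spec.input_dim,), seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 42) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for _ in range(spec.n_stages):
        layers += [
            nn.Conv2d(spec.conv_channels, spec.conv_kernel, stride=2,
                      padding="same", bias=False),
            nn.LeakyReLU(spec.activation_slope),
            nn.Dropout(spec.dropout_rate),
        ]
    layers += [nn.Flatten(), nn.Dense(1, bias=True), nn.Sigmoid()]
    return nn.Sequential(
        layers, input_shape=(1, spec.input_side, spec.input_side), seed=seed
    )


def build_gan(gen_spec: GeneratorSpec | None = None,
              disc_spec: DiscriminatorSpec | None = None,
              seed: int = 42) -> GanPair:
    gen_spec = gen_spec or GeneratorSpec()
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(input_side=gen_spec.output_side,
                                      profile=gen_spec.profile)
    return GanPair(
        generator=build_generator(gen_spec, seed=seed),
        discriminator=build_discriminator(disc_spec, seed=seed + 1),
        gen_spec=gen_spec,
        disc_spec=disc_spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass
class GanBatchLoss:
    """Discriminator and generator binary cross-entropy terms for one batch."""

    d_loss_real: float
    d_loss_fake: float
    g_loss: float

    @property
    def d_loss(self) -> float:
        return self.d_loss_real + self.d_loss_fake


def gan_loss(d_real, d_fake) -> GanBatchLoss:
    """Adversarial losses from discriminator probabilities.

    Discriminator: -mean log D(x) - mean log(1 - D(G(y))); generator uses
    the non-saturating form -mean log D(G(y)).  Probabilities are clamped
    at 1e-7 from both ends.
    """
    p_real = np.clip(np.asarray(d_real, dtype=float), nn.PROB_EPS, 1 - nn.PROB_EPS)
    p_fake = np.clip(np.asarray(d_fake, dtype=float), nn.PROB_EPS, 1 - nn.PROB_EPS)
    return GanBatchLoss(
        d_loss_real=float(-np.log(p_real).mean()),
        d_loss_fake=float(-np.log(1.0 - p_fake).mean()),
        g_loss=float(-np.log(p_fake).mean()),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class GanTrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 16
    iterations: int = 200
    seed: int = 42
    recon_weight: float = 1.0  # pixel-wise BCE reconstruction term weight
    track_metrics: bool = False  # per-iteration SSIM/CC against targets
    n_probe: int = 8  # pairs used for metric tracking


RECON_EPS = 1e-3  # clamp for the pixel reconstruction cross-entropy


def _make_optimizer(network, config: GanTrainConfig, lr_factor: float = 1.0):
    lr = config.learning_rate * lr_factor
    if config.optimizer.lower() == "adam":
        return nn.Adam(network, lr=lr)
    if config.optimizer.lower() == "sgd":
        return nn.SGD(network, lr=lr)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def train_adversarial(pair: GanPair, inputs, reals,
                      config: GanTrainConfig | None = None,
                      lr_factor: float = 1.0) -> pd.DataFrame:
    """Alternating single D / single G steps per batch.

    ``inputs`` are the generator inputs (N, input_dim) paired by index with
    the real images ``reals`` (N, H, W) in [0, 1].  The generator minimises
    the non-saturating adversarial loss plus ``recon_weight`` times a
    pixel-wise binary cross-entropy against its paired target — the pairing
    signal without which a feature vector could fool the discriminator with
    any class's image.  With ``track_metrics`` the history additionally
    carries per-iteration mean SSIM and CC of generated maps against their
    paired targets on a fixed probe subset.  Raises
    :class:`~eegsaliency.classifier.DivergenceError` on non-finite losses.
    """
    from .classifier import DivergenceError

    config = config or GanTrainConfig()
    gen, disc = pair.generator, pair.discriminator
    inputs = np.asarray(inputs, dtype=float)
    reals = np.asarray(reals, dtype=float)
    if inputs.shape[0] != reals.shape[0]:
        raise ValueError("inputs and real images must be aligned")
    if inputs.shape[0] < 1:
        raise ValueError("need at least one training pair")
    x_real = reals[:, None, :, :]
    opt_d = _make_optimizer(disc, config, lr_factor)
    opt_g = _make_optimizer(gen, config, lr_factor)
    rng = np.random.default_rng(config.seed)
    probe_idx = np.arange(min(config.n_probe, inputs.shape[0]))
    ssim_params = SSIMParams(K=1.0)
    history = []
    for it in range(config.iterations):
        idx = rng.integers(0, inputs.shape[0], size=config.batch_size)
        # --- discriminator step on a combined real+fake batch
        fake = gen.forward(inputs[idx], training=True)
        batch = np.concatenate([x_real[idx], fake])
        targets = np.concatenate([np.ones(len(idx)), np.zeros(len(idx))])
        probs = disc.forward(batch, training=True)[:, 0]
        d_loss, d_grad = nn.bce_loss(probs, targets)
        disc.backward(d_grad[:, None].astype(disc.dtype))
        opt_d.step()
        # --- generator step (non-saturating adversarial + paired pixel BCE)
        fake = gen.forward(inputs[idx], training=True)
        p_fake = disc.forward(fake, training=True)[:, 0]
        p = np.clip(p_fake, nn.PROB_EPS, 1 - nn.PROB_EPS)
        g_adv = float(-np.log(p).mean())
        g_grad = (-1.0 / (p * p.size))[:, None]
        g_img = disc.backward(g_grad.astype(disc.dtype))
        g_recon = 0.0
        if config.recon_weight:
            # straight-through pixel BCE: out-of-range intensities use the
            # boundary gradient, so dark pixels still get pushed upward
            pr = np.clip(fake, RECON_EPS, 1 - RECON_EPS)
            t = x_real[idx]
            g_recon = float(-(t * np.log(pr) + (1 - t) * np.log(1 - pr)).mean())
            recon_grad = (-(t / pr) + (1 - t) / (1 - pr)) / fake.size
            g_img = g_img + config.recon_weight * recon_grad
        gen.backward(g_img.astype(gen.dtype))
        opt_g.step()
        g_loss = g_adv + config.recon_weight * g_recon
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise DivergenceError(it)
        row = {"iteration": it, "d_loss": d_loss, "g_loss": g_adv,
               "g_recon": g_recon}
        if config.track_metrics:
            s, c = evaluate_against_targets(
                pair, inputs[probe_idx], reals[probe_idx], ssim_params
            )
            row["ssim"], row["cc"] = s, c
        history.append(row)
    return pd.DataFrame(history)


def evaluate_against_targets(pair: GanPair, inputs, targets,
                             ssim_params: SSIMParams | None = None):
    """Mean SSIM and CC of generated maps against paired target images."""
    ssim_params = ssim_params or SSIMParams(K=1.0)
    out = pair.generator.forward(np.asarray(inputs, dtype=float))[:, 0]
    out = np.clip(out, 0.0, None)
    targets = np.asarray(targets, dtype=float)
    s_vals = [ssim(o, t, ssim_params) for o, t in zip(out, targets)]
    c_vals = [cc(o, t) for o, t in zip(out, targets)]
    return float(np.mean(s_vals)), float(np.nanmean(c_vals))


def train_gan(features, targets, gen_spec: GeneratorSpec | None = None,
              config: GanTrainConfig | None = None):
    """Train the saliency GAN on paired (feature vector, target map) data.

    ``targets`` may be SaliencyMap objects or raw 2-D arrays; each is scaled
    to unit maximum before training so the generator works on an image-like
    intensity range.  Returns (GanPair, history DataFrame).
    """
    config = config or GanTrainConfig()
    features = np.asarray(features, dtype=float)
    target_arr = np.stack([map_to_image(t) for t in targets])
    if gen_spec is None:
        gen_spec = GeneratorSpec.desk(input_dim=features.shape[1])
    if features.shape[1] != gen_spec.input_dim:
        raise ValueError(
            f"feature length {features.shape[1]} != generator input "
            f"{gen_spec.input_dim}"
        )
    if target_arr.shape[1] != gen_spec.output_side:
        raise ValueError(
            f"target side {target_arr.shape[1]} != generator output "
            f"{gen_spec.output_side}"
        )
    pair = build_gan(gen_spec, seed=config.seed)
    history = train_adversarial(pair, features, target_arr, config)
    return pair, history


def map_to_image(target) -> np.ndarray:
    """A map rescaled to peak intensity 1 (images pass through unchanged)."""
    values = target.values if hasattr(target, "values") else np.asarray(target)
    values = np.asarray(values, dtype=float)
    peak = values.max()
    return values / peak if peak > 0 else values


def generate_saliency(generator: nn.Sequential | GanPair, feature) -> SaliencyMap:
    """Run the generator on one feature vector; clamp the map at zero."""
    gen = generator.generator if isinstance(generator, GanPair) else generator
    feature = np.asarray(feature, dtype=float)
    single = feature.ndim == 1
    out = gen.forward(feature[None] if single else feature)
    out = np.clip(out[:, 0], 0.0, None)
    return SaliencyMap(out[0]) if single else [SaliencyMap(o) for o in out]
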