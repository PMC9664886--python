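"""Conditional GAN mapping fringe images to optical-property maps.

The generator is a compact U-Net with long skip connections
(encoder->decoder concatenation) and short residual skips within each level;
the decoder upsamples by nearest-neighbour + convolution.  The discriminator
is a three-layer strided convolutional patch classifier with leaky ReLUs and
spectral normalisation, conditioned on the input by channel concatenation.

Training follows the least-squares adversarial objective with real label 1
and fake label 0,

    L_D = E[(D(x, y) - 1)^2] + E[D(x, G(x))^2]
    L_G = E[(D(x, G(x)) - 1)^2] + lambda * E[ ||y - G(x)||_1 ],

with lambda = 60, Adam at 1e-4 held for the first half of the epochs and
decayed linearly to zero over the second half, all weights initialised from
N(0, 0.02^2), and a 64-pair history buffer of previously generated pairs
mixed into the discriminator's fake batch.  Everything is reproducible from
the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field as dc_field

import numpy as np
import pandas as pd

from .nn import (Adam, Conv2d, InstanceNorm2d, LeakyReLU, ReLU, Sequential,
                 SpectralNorm, Tanh, Upsample2x)
from .scenes import ConfigError

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "TrainConfig", "HistoryBuffer",
    "UNetGenerator", "build_generator", "build_discriminator",
    "adversarial_loss", "l1_loss", "total_generator_loss",
    "learning_rate", "train", "predict", "TrainingDivergedError",
    "save_checkpoint", "load_checkpoint", "samples_to_arrays",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; training aborted."""


def _check_size(size: int) -> None:
    if size < 32 or (size & (size - 1)) != 0:
        raise ConfigError(f"image size must be a power of two >= 32, got {size}")


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyper-parameters; depth scales with the input size."""

    size: int = 256
    base_channels: int = 16
    max_channels: int = 64
    levels: int | None = None
    short_skip: bool = True
    long_skip: bool = True
    instance_norm: bool = True
    """Per-image feature normalisation in the generator.  The absolute
    fringe amplitude (which carries the optical properties) still reaches
    the decoder through the long skip connections, and normalising the
    interior features conditions the optimisation markedly better than
    leaving them raw."""
    final_activation: str = "tanh"  # "tanh" or "linear"
    """A linear head avoids the saturation floor at the channel extremes
    (the blue channel's constant-zero target maps exactly onto tanh's
    asymptote)."""

    def __post_init__(self):
        _check_size(self.size)

    @property
    def n_levels(self) -> int:
        if self.levels is not None:
            return self.levels
        return max(2, int(math.log2(self.size)) - 3)

    @property
    def channels(self) -> list:
        return [min(self.base_channels * 2**i, self.max_channels)
                for i in range(self.n_levels + 1)]


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Three-layer strided patch classifier on the concatenated (x, y) pair."""

    size: int = 256
    base_channels: int = 16
    leaky_slope: float = 0.2
    spectral_norm: bool = True

    def __post_init__(self):
        _check_size(self.size)


@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-4
    lambda_l1: float = 60.0
    batch_size: int = 1
    adam_betas: tuple = (0.9, 0.999)
    seed: int = 0
    buffer_capacity: int = 64
    generator: GeneratorSpec = dc_field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = dc_field(default_factory=DiscriminatorSpec)

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ConfigError("lambda_l1 must be >= 0")
        if self.epochs % 2 != 0:
            raise ConfigError("epochs must be even (half constant, half decayed)")


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Constant for epochs 1..E/2, then linear to zero at epoch E."""
    half = config.epochs // 2
    if epoch <= half:
        return config.lr
    return config.lr * (config.epochs - epoch) / half


# ---------------------------------------------------------------------------
# generator

class _Identity:
    """No-op stand-in for a disabled normalisation layer."""

    def params(self):
        return []

    def forward(self, x, train=True):
        return x

    def backward(self, dy):
        return dy


def _norm(channels: int, enabled: bool):
    return InstanceNorm2d(channels) if enabled else _Identity()


class _ResBlock:
    """Short skip within a level: y = lrelu(x + conv(lrelu(conv(x))))."""

    def __init__(self, channels: int, rng, norm: bool = False):
        self.conv1 = Conv2d(channels, channels, 3, 1, rng)
        self.n1 = _norm(channels, norm)
        self.a1 = LeakyReLU(0.2)
        self.conv2 = Conv2d(channels, channels, 3, 1, rng)
        self.n2 = _norm(channels, norm)
        self.a2 = LeakyReLU(0.2)

    def params(self):
        return (self.conv1.params() + self.n1.params()
                + self.conv2.params() + self.n2.params())

    def forward(self, x, train=True):
        h = self.a1.forward(self.n1.forward(self.conv1.forward(x, train), train), train)
        h = self.n2.forward(self.conv2.forward(h, train), train)
        return self.a2.forward(x + h, train)

    def backward(self, dy):
        ds = self.a2.backward(dy)
        dh = self.n2.backward(ds)
        dh = self.conv2.backward(dh)
        dh = self.a1.backward(dh)
        dh = self.n1.backward(dh)
        dh = self.conv1.backward(dh)
        return ds + dh


class UNetGenerator:
    """Encoder/decoder with long skips and per-level residual blocks."""

    def __init__(self, spec: GeneratorSpec, rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        ch = spec.channels
        self.stem = Conv2d(3, ch[0], 3, 1, rng)
        self.stem_act = LeakyReLU(0.2)
        self.downs, self.down_norms, self.down_acts, self.res = [], [], [], []
        for i in range(spec.n_levels):
            self.downs.append(Conv2d(ch[i], ch[i + 1], 3, 2, rng))
            self.down_norms.append(_norm(ch[i + 1], spec.instance_norm))
            self.down_acts.append(LeakyReLU(0.2))
            self.res.append(_ResBlock(ch[i + 1], rng, spec.instance_norm)
                            if spec.short_skip else None)
        self.ups, self.up_convs, self.up_norms, self.up_acts = [], [], [], []
        for i in range(spec.n_levels, 0, -1):
            c_in = ch[i] + (ch[i - 1] if spec.long_skip else 0)
            self.ups.append(Upsample2x())
            self.up_convs.append(Conv2d(c_in, ch[i - 1], 3, 1, rng))
            self.up_norms.append(_norm(ch[i - 1], spec.instance_norm))
            self.up_acts.append(ReLU())
        self.head = Conv2d(ch[0], 3, 3, 1, rng)
        if spec.final_activation == "tanh":
            self.out_act = Tanh()
        elif spec.final_activation == "linear":
            self.out_act = _Identity()
        else:
            raise ConfigError(f"unknown final activation {spec.final_activation!r}")

    def params(self):
        ps = self.stem.params()
        for i in range(self.spec.n_levels):
            ps += self.downs[i].params() + self.down_norms[i].params()
            if self.res[i] is not None:
                ps += self.res[i].params()
        for j in range(len(self.up_convs)):
            ps += self.up_convs[j].params() + self.up_norms[j].params()
        return ps + self.head.params()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, train: bool = True):
        L = self.spec.n_levels
        feats = [self.stem_act.forward(self.stem.forward(x, train), train)]
        h = feats[0]
        for i in range(L):
            h = self.down_acts[i].forward(
                self.down_norms[i].forward(self.downs[i].forward(h, train), train), train)
            if self.res[i] is not None:
                h = self.res[i].forward(h, train)
            feats.append(h)
        self._split = []
        d = feats[L]
        for j, i in enumerate(range(L, 0, -1)):
            d = self.ups[j].forward(d, train)
            if self.spec.long_skip:
                self._split.append(d.shape[1])
                d = np.concatenate([d, feats[i - 1]], axis=1)
            d = self.up_acts[j].forward(
                self.up_norms[j].forward(self.up_convs[j].forward(d, train), train), train)
        return self.out_act.forward(self.head.forward(d, train), train)

    def backward(self, dy):
        L = self.spec.n_levels
        dd = self.head.backward(self.out_act.backward(dy))
        skip_grads = [None] * (L + 1)
        for j in reversed(range(L)):
            i = L - j  # encoder level whose output fed decoder stage j
            dd = self.up_convs[j].backward(
                self.up_norms[j].backward(self.up_acts[j].backward(dd)))
            if self.spec.long_skip:
                c = self._split[j]
                dskip = dd[:, c:]
                dd = dd[:, :c]
                if skip_grads[i - 1] is None:
                    skip_grads[i - 1] = dskip.copy()
                else:
                    skip_grads[i - 1] += dskip
            dd = self.ups[j].backward(dd)
        dh = dd  # gradient flowing into feats[L]
        for i in reversed(range(L)):
            if skip_grads[i + 1] is not None:
                dh = dh + skip_grads[i + 1]
            if self.res[i] is not None:
                dh = self.res[i].backward(dh)
            dh = self.downs[i].backward(
                self.down_norms[i].backward(self.down_acts[i].backward(dh)))
        if skip_grads[0] is not None:
            dh = dh + skip_grads[0]
        return self.stem.backward(self.stem_act.backward(dh))


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    """Generator with all weights drawn N(0, 0.02^2) from the seed."""
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Sequential:
    """Three conv layers (two strided) with leaky ReLUs; patch score output."""
    rng = np.random.default_rng(seed)
    conv = SpectralNorm if spec.spectral_norm else Conv2d
    c = spec.base_channels
    return Sequential(
        conv(6, c, 4, 2, rng), LeakyReLU(spec.leaky_slope),
        conv(c, 2 * c, 4, 2, rng), LeakyReLU(spec.leaky_slope),
        conv(2 * c, 1, 4, 1, rng),
    )


# ---------------------------------------------------------------------------
# losses

def adversarial_loss(d_real_scores, d_fake_scores, side: str) -> float:
    """Least-squares adversarial objective (real label 1, fake label 0)."""
    if side == "discriminator":
        if d_real_scores is None:
            raise ValueError("discriminator side needs real scores")
        loss = (np.mean((np.asarray(d_real_scores) - 1.0) ** 2)
                + np.mean(np.asarray(d_fake_scores) ** 2))
    elif side == "generator":
        loss = np.mean((np.asarray(d_fake_scores) - 1.0) ** 2)
    else:
        raise ValueError(f"side must be 'generator' or 'discriminator', got {side!r}")
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite adversarial loss")
    return float(loss)


def l1_loss(truth, generated) -> float:
    truth = np.asarray(truth, dtype=np.float32)
    generated = np.asarray(generated, dtype=np.float32)
    if truth.shape != generated.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {generated.shape}")
    return float(np.mean(np.abs(truth - generated)))


def total_generator_loss(adv: float, l1: float, lambda_l1: float) -> float:
    total = adv + lambda_l1 * l1
    if not np.isfinite(total):
        raise TrainingDivergedError("non-finite generator loss")
    return float(total)


# ---------------------------------------------------------------------------
# history buffer

class HistoryBuffer:
    """Pool of up to 64 previously generated (x, G(x)) pairs.

    New pairs displace uniformly random old ones once the pool is full;
    sampling is uniform over the current contents.
    """

    def __init__(self, capacity: int = 64, seed: int = 0):
        self.capacity = capacity
        self._rng = np.random.default_rng(seed)
        self._x, self._y = [], []

    def __len__(self):
        return len(self._x)

    def push(self, x_batch, y_batch):
        for x, y in zip(x_batch, y_batch):
            if len(self._x) < self.capacity:
                self._x.append(x.copy())
                self._y.append(y.copy())
            else:
                k = int(self._rng.integers(self.capacity))
                self._x[k] = x.copy()
                self._y[k] = y.copy()

    def sample(self, n: int):
        idx = self._rng.integers(len(self._x), size=n)
        return (np.stack([self._x[i] for i in idx]),
                np.stack([self._y[i] for i in idx]))


# ---------------------------------------------------------------------------
# training

def samples_to_arrays(samples):
    """PairedSamples -> (x, y) float32 arrays in [-1, 1], NCHW."""
    x = np.stack([s.input_half for s in samples]).astype(np.float32)
    y = np.stack([s.truth_half for s in samples]).astype(np.float32)
    x = x.transpose(0, 3, 1, 2) / 127.5 - 1.0
    y = y.transpose(0, 3, 1, 2) / 127.5 - 1.0
    return x, y


def _validate(gen, x_val, y_val, batch: int):
    l1s, mses = [], []
    for i in range(0, len(x_val), batch):
        out = gen.forward(x_val[i:i + batch], train=False)
        diff = out - y_val[i:i + batch]
        l1s.append(np.mean(np.abs(diff)))
        mses.append(np.mean(diff**2))
    return float(np.mean(l1s)), float(np.mean(mses))


def train(train_samples, val_samples, config: TrainConfig, progress: bool = False):
    """Train the conditional GAN; returns (generator, per-epoch history)."""
    if len(train_samples) == 0:
        raise ConfigError("empty training split")
    x_tr, y_tr = samples_to_arrays(train_samples)
    x_val, y_val = (samples_to_arrays(val_samples) if len(val_samples)
                    else (x_tr[:1], y_tr[:1]))
    gen = build_generator(config.generator, seed=config.seed)
    disc = build_discriminator(config.discriminator, seed=config.seed + 1)
    opt_g = Adam(gen.params(), lr=config.lr, betas=config.adam_betas)
    opt_d = Adam([p for p in _seq_params(disc)], lr=config.lr, betas=config.adam_betas)
    pool = HistoryBuffer(config.buffer_capacity, seed=config.seed + 2)
    shuffle_rng = np.random.default_rng(config.seed + 3)
    lam = config.lambda_l1
    rows = []
    for epoch in range(1, config.epochs + 1):
        lr = learning_rate(epoch, config)
        opt_g.lr = opt_d.lr = lr
        order = shuffle_rng.permutation(len(x_tr))
        d_losses, g_advs, g_l1s = [], [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            fake = gen.forward(xb, train=True)

            # --- discriminator update (fakes treated as constants)
            opt_d.zero_grad()
            d_real = disc.forward(np.concatenate([xb, yb], axis=1), train=True)
            disc.backward(2.0 * (d_real - 1.0) / d_real.size)
            d_fake = disc.forward(np.concatenate([xb, fake], axis=1), train=True)
            disc.backward(0.5 * 2.0 * d_fake / d_fake.size)
            pool.push(xb, fake)
            xp, yp = pool.sample(len(xb))
            d_pool = disc.forward(np.concatenate([xp, yp], axis=1), train=True)
            disc.backward(0.5 * 2.0 * d_pool / d_pool.size)
            d_loss = adversarial_loss(d_real, d_fake, "discriminator")
            opt_d.step()

            # --- generator update through the refreshed discriminator
            gen.zero_grad()
            d_fake2 = disc.forward(np.concatenate([xb, fake], axis=1), train=True)
            g_adv = adversarial_loss(None, d_fake2, "generator")
            dxy = disc.backward(2.0 * (d_fake2 - 1.0) / d_fake2.size)
            l1 = l1_loss(yb, fake)
            total_generator_loss(g_adv, l1, lam)  # finiteness guard
            dfake = dxy[:, 3:] + lam * np.sign(fake - yb) / fake.size
            gen.backward(dfake.astype(np.float32))
            opt_g.step()

            d_losses.append(d_loss)
            g_advs.append(g_adv)
            g_l1s.append(l1)
        val_l1, val_mse = _validate(gen, x_val, y_val, config.batch_size)
        rows.append({"epoch": epoch, "lr": lr, "d_loss": float(np.mean(d_losses)),
                     "g_adv": float(np.mean(g_advs)), "g_l1": float(np.mean(g_l1s)),
                     "val_l1": val_l1, "val_mse": val_mse})
        if progress:
            r = rows[-1]
            print(f"epoch {epoch:3d}  lr {lr:.2e}  d {r['d_loss']:.3f} "
                  f"adv {r['g_adv']:.3f}  l1 {r['g_l1']:.4f}  val_l1 {val_l1:.4f}")
    return gen, pd.DataFrame(rows)


def _seq_params(seq: Sequential):
    return seq.params()


def predict(generator: UNetGenerator, image) -> np.ndarray:
    """Deterministic inference: 8-bit H x W x 3 property-map prediction."""
    from .render import SfdiImage

    if isinstance(image, SfdiImage):
        arr = image.quantise()
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
    if arr.shape[0] != generator.spec.size or arr.shape[1] != generator.spec.size:
        raise ValueError(f"generator expects {generator.spec.size}px inputs, "
                         f"got {arr.shape[:2]}")
    x = arr.astype(np.float32).transpose(2, 0, 1)[None] / 127.5 - 1.0
    out = generator.forward(x, train=False)[0].transpose(1, 2, 0)
    return np.floor(np.clip((out + 1.0) * 127.5, 0, 255) + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(generator: UNetGenerator, path, config: TrainConfig | None = None):
    arrays = {f"p{i}": p.data for i, p in enumerate(generator.params())}
    meta = {"generator": asdict(generator.spec)}
    if config is not None:
        meta["train"] = {k: v for k, v in asdict(config).items()
                         if k not in ("generator", "discriminator")}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> UNetGenerator:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    gen = build_generator(GeneratorSpec(**meta["generator"]))
    for i, p in enumerate(gen.params()):
        p.data[...] = data[f"p{i}"]
    return gen
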