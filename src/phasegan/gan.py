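"""Three-player adversarial–cooperative model for imbalanced spectra.

Three networks are trained jointly on class-imbalanced 1-D spectra that have
been min-max normalized to [-1, 1] and reshaped onto a 2-D grid:

* a class-conditional **generator** G(z, y) mapping a latent vector and a
  label embedding to a spectrum grid in [-1, 1] (tanh output);
* a class-conditional **discriminator** (Wasserstein critic) D(x, y) scored
  with a gradient penalty that drives its input-gradient norm toward 1 on
  interpolates of real and generated samples;
* a **classifier** C(x) trained by cross-entropy on *balanced* batches in
  which each minority-class deficit is filled with generator outputs.

Adversarial learning (G vs D) makes generated spectra realistic;
cooperative learning (G with C) adds the classifier's cross-entropy on
generated samples to the generator objective so the samples are also
class-distinguishable.  Training starts from an autoencoder-style
initialization: an encoder sharing the discriminator trunk maps spectra to
the latent space and the generator acts as decoder, trained by mean-squared
reconstruction.

All stochastic draws descend from a single seeded root generator with named
substreams, so a full run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict, replace as dataclass_replace

import numpy as np

from . import nn
from .augment import register_augmenter
from .spectra import SpectralDataset, Spectrum, MinMaxNormalizer, most_square_grid

__all__ = ["ThreePlayerConfig", "PlayerBundle", "TrainLog", "build_players",
           "gradient_penalty", "pretrain", "assemble_balanced_batch",
           "train_step", "train", "train_classifier", "generate_minority",
           "extract_features", "predict_proba", "predict_labels",
           "save_players", "load_players"]


@dataclass
class ThreePlayerConfig:
    """All architecture / optimizer / training constants.

    Defaults follow the published hyperparameter tables for this model
    family: Adam(lr 2e-4, beta1 0.5, beta2 0.9), gradient-penalty
    coefficient 10, 4 conv blocks per network with 4x4 kernels, stride 2,
    "same" padding, LeakyReLU slope 0.2, random-normal init sd 0.02,
    150 training epochs after 100 reconstruction pre-training epochs.
    ``reshape`` maps a length-L spectrum onto a rows x cols grid (default:
    most-square factorization, e.g. 800 -> 25x32).
    """

    epochs: int = 150
    pretrain_epochs: int = 100
    learning_rate: float = 2e-4
    gen_learning_rate: float | None = None  # two-timescale option; None = learning_rate
    beta1: float = 0.5
    beta2: float = 0.9
    gp_coefficient: float = 10.0
    latent_dim: int = 128
    batch_size: int = 32
    leaky_slope: float = 0.2
    init_sd: float = 0.02
    disc_kernels: tuple = (64, 128, 128, 256)
    gen_kernels: tuple = (128, 128, 64)      # hidden blocks; final block -> 1 channel
    gen_initial_channels: int = 256
    clf_kernels: tuple = (32, 32, 128, 256)
    kernel_size: int = 4
    stride: int = 2
    reshape: tuple | None = None
    cooperative_weight: float = 1.0
    feature_match_weight: float = 1.0
    n_critic: int = 1
    critic_warmup_epochs: int = 10
    ema_decay: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gp_coefficient < 0:
            raise ValueError("gp_coefficient must be >= 0")
        for name in ("epochs", "pretrain_epochs", "latent_dim", "batch_size"):
            if getattr(self, name) < 0 or (name in ("latent_dim", "batch_size")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")

    def grid(self, length: int) -> tuple[int, int]:
        shape = tuple(self.reshape) if self.reshape else most_square_grid(length)
        if shape[0] * shape[1] != length:
            raise ValueError(f"reshape {shape} incompatible with length {length}")
        return shape

    @classmethod
    def scaled_down(cls, **overrides) -> "ThreePlayerConfig":
        """Desk-scale preset: same structure, smaller widths and budgets."""
        base = dict(epochs=40, pretrain_epochs=30, latent_dim=32,
                    disc_kernels=(16, 32, 32, 64), gen_kernels=(32, 32, 16),
                    gen_initial_channels=64, clf_kernels=(16, 16, 32, 64))
        base.update(overrides)
        return cls(**base)


def _shape_ladder(grid: tuple[int, int], n_blocks: int = 4) -> list[tuple[int, int]]:
    shapes = [tuple(grid)]
    for _ in range(n_blocks):
        shapes.append(nn.conv_output_shape(shapes[-1]))
    return shapes


class _ConvTrunk:
    """Shared structure: 4 blocks of [Conv2D, LeakyReLU] then Flatten."""

    def __init__(self, kernels, grid, config, rng):
        shapes = _shape_ladder(grid)
        layers = []
        cin = 1
        for i, cout in enumerate(kernels):
            layers.append(nn.Conv2D(cin, cout, shapes[i], rng, k=config.kernel_size,
                                    stride=config.stride, init_sd=config.init_sd))
            layers.append(nn.LeakyReLU(config.leaky_slope))
            cin = cout
        layers.append(nn.Flatten())
        self.seq = nn.Sequential(layers)
        self.flat_dim = kernels[-1] * shapes[-1][0] * shapes[-1][1]

    def forward(self, x, train=True):
        return self.seq.forward(x, train=train)

    def backward(self, gout):
        return self.seq.backward(gout)

    def params(self):
        return self.seq.params()


class Discriminator:
    """Class-conditional Wasserstein critic with one score output per class.

    D(x, y) selects class y's column of a multi-output linear head over the
    shared conv-trunk features, so each class has its own critic score.
    With very small minority classes this matters: a single shared score
    with weak label coupling degenerates into an unconditional critic whose
    transport field pushes minority-conditioned samples toward the majority
    mass; per-class scores keep each class's real-vs-generated comparison
    self-contained.
    """

    def __init__(self, config, n_classes, grid, rng):
        self.trunk = _ConvTrunk(config.disc_kernels, grid, config, rng)
        self.head = nn.Dense(self.trunk.flat_dim, n_classes, rng,
                             init_sd=config.init_sd)
        self.n_classes = n_classes
        self._labels = None

    def params(self):
        return self.trunk.params() + self.head.params()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, labels, train=True):
        self._labels = np.asarray(labels, dtype=int)
        flat = self.trunk.forward(x, train=train)
        scores = self.head.forward(flat)
        return scores[np.arange(len(self._labels)), self._labels][:, None]

    def backward(self, gscore):
        gall = np.zeros((gscore.shape[0], self.n_classes))
        gall[np.arange(len(self._labels)), self._labels] = gscore.ravel()
        return self.trunk.backward(self.head.backward(gall))

    def bn_stats(self):
        return []


class Classifier:
    """CNN classifier: conv trunk then a dense softmax head."""

    def __init__(self, config, n_classes, grid, rng):
        self.trunk = _ConvTrunk(config.clf_kernels, grid, config, rng)
        self.head = nn.Dense(self.trunk.flat_dim, n_classes, rng,
                             init_sd=config.init_sd)
        self._features = None

    def params(self):
        return self.trunk.params() + self.head.params()

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, train=True):
        self._features = self.trunk.forward(x, train=train)
        return self.head.forward(self._features)

    def backward(self, glogits):
        gflat = self.head.backward(glogits)
        return self.trunk.backward(gflat)

    def features(self, x):
        """Penultimate-layer activations (input to the softmax head)."""
        return self.trunk.forward(x, train=False)

    def bn_stats(self):
        return []


class Generator:
    """Conditional generator: (z, label) -> spectrum grid in [-1, 1]."""

    def __init__(self, config, n_classes, grid, rng):
        shapes = _shape_ladder(grid)
        self.embed = nn.Embedding(n_classes, config.latent_dim, rng,
                                  init_sd=config.init_sd)
        c0 = config.gen_initial_channels
        self.h0w0 = shapes[-1]
        self.c0 = c0
        self.project = nn.Dense(2 * config.latent_dim,
                                c0 * shapes[-1][0] * shapes[-1][1], rng,
                                init_sd=config.init_sd)
        self.project_act = nn.LeakyReLU(config.leaky_slope)
        blocks = []
        cin = c0
        channels = list(config.gen_kernels) + [1]
        for i, cout in enumerate(channels):
            conv = nn.ConvTranspose2D(cin, cout, shapes[4 - i], shapes[3 - i], rng,
                                      k=config.kernel_size, stride=config.stride,
                                      init_sd=config.init_sd)
            blocks.append(conv)
            if i < len(channels) - 1:
                blocks.append(nn.LeakyReLU(config.leaky_slope))
                blocks.append(nn.BatchNorm2D(cout))
            else:
                blocks.append(nn.Tanh())
            cin = cout
        self.blocks = nn.Sequential(blocks)
        self.latent_dim = config.latent_dim
        # per-class latent prior; refitted from the encoder during pretraining
        self.latent_mean = np.zeros((n_classes, config.latent_dim))
        self.latent_sd = np.ones((n_classes, config.latent_dim))

    def sample_latent(self, label_idx, rng: np.random.Generator) -> np.ndarray:
        """Draw z from the class-conditional latent prior N(mu_y, sd_y^2)."""
        label_idx = np.asarray(label_idx, dtype=int)
        eps = rng.standard_normal((label_idx.size, self.latent_dim))
        return self.latent_mean[label_idx] + self.latent_sd[label_idx] * eps

    def params(self):
        return (self.embed.params() + self.project.params() + self.blocks.params())

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, z, labels, train=True):
        emb = self.embed.forward(labels)
        h = self.project.forward(np.concatenate([z, emb], axis=1))
        h = self.project_act.forward(h)
        h = h.reshape(z.shape[0], self.c0, *self.h0w0)
        return self.blocks.forward(h, train=train)

    def backward(self, ggrid):
        gh = self.blocks.backward(ggrid)
        gh = gh.reshape(gh.shape[0], -1)
        gh = self.project_act.backward(gh)
        gcat = self.project.backward(gh)
        gz, gemb = gcat[:, :self.latent_dim], gcat[:, self.latent_dim:]
        self.embed.backward(gemb)
        return gz

    def bn_stats(self):
        stats = []
        for layer in self.blocks.layers:
            if isinstance(layer, nn.BatchNorm2D):
                stats.extend([layer.running_mean, layer.running_var])
        return stats + [self.latent_mean, self.latent_sd]


@dataclass
class PlayerBundle:
    """The three trained (or trainable) networks plus their optimizers."""

    generator: Generator
    discriminator: Discriminator
    classifier: Classifier
    config: ThreePlayerConfig
    classes: list[str]
    grid: tuple[int, int]
    opt_g: nn.Adam = None
    opt_d: nn.Adam = None
    opt_c: nn.Adam = None
    # slowly tracking copy of the generator; serves all generated samples so
    # that early, noisy adversarial updates cannot wipe out the pretrained state
    ema_generator: Generator = None
    # measurement-noise scale (normalized units) estimated from within-class
    # residuals of the training data; added to served generator samples so the
    # classifier cannot tell real from generated by noise level alone
    noise_sd: float = 0.0

    def sync_ema(self) -> None:
        for pe, p in zip(self.ema_generator.params(), self.generator.params()):
            pe.value[...] = p.value
        for se, s in zip(self.ema_generator.bn_stats(), self.generator.bn_stats()):
            se[...] = s

    def update_ema(self, decay: float) -> None:
        for pe, p in zip(self.ema_generator.params(), self.generator.params()):
            pe.value *= decay
            pe.value += (1.0 - decay) * p.value
        for se, s in zip(self.ema_generator.bn_stats(), self.generator.bn_stats()):
            se *= decay
            se += (1.0 - decay) * s

    @property
    def length(self) -> int:
        return self.grid[0] * self.grid[1]

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return values.reshape(values.shape[0], 1, *self.grid)

    def to_flat(self, grids: np.ndarray) -> np.ndarray:
        return grids.reshape(grids.shape[0], -1)

    def label_index(self, labels) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[l] for l in labels], dtype=int)


@dataclass
class TrainLog:
    """Per-epoch training records; one dict per completed epoch."""

    records: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.records, sort_keys=True)


def build_players(config: ThreePlayerConfig, n_classes: int, length: int,
                  classes: list[str] | None = None) -> PlayerBundle:
    """Construct the three networks with seeded random-normal initialization."""
    grid = config.grid(length)
    root = np.random.SeedSequence(config.seed)
    ss_g, ss_d, ss_c = root.spawn(3)
    gen = Generator(config, n_classes, grid, np.random.default_rng(ss_g))
    disc = Discriminator(config, n_classes, grid, np.random.default_rng(ss_d))
    clf = Classifier(config, n_classes, grid, np.random.default_rng(ss_c))
    adam = dict(lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    if classes is None:
        classes = [str(i) for i in range(n_classes)]
    adam_g = dict(adam, lr=config.gen_learning_rate or config.learning_rate)
    bundle = PlayerBundle(gen, disc, clf, config, list(classes), grid,
                          opt_g=nn.Adam(gen.params(), **adam_g),
                          opt_d=nn.Adam(disc.params(), **adam),
                          opt_c=nn.Adam(clf.params(), **adam),
                          ema_generator=copy.deepcopy(gen))
    bundle.sync_ema()
    return bundle


# ---------------------------------------------------------------------------
# Gradient penalty
# ---------------------------------------------------------------------------

def _input_gradients(disc: Discriminator, x, labels) -> np.ndarray:
    """Per-sample gradient of the critic score w.r.t. its input.

    Leaves parameter gradients untouched (snapshot/restore around the pass).
    """
    params = disc.params()
    saved = [p.grad.copy() for p in params]
    disc.forward(x, labels, train=True)
    gx = disc.backward(np.ones((x.shape[0], 1)))
    for p, s in zip(params, saved):
        p.grad[...] = s
    return gx


def gradient_penalty(discriminator: Discriminator, real_batch, fake_batch, labels,
                     lam: float, seed: int = 0) -> float:
    """lambda * mean((||grad_x D(x_hat, y)||_2 - 1)^2) on random interpolates.

    x_hat = eps*real + (1-eps)*fake with eps ~ Uniform(0,1) per sample.
    """
    real_batch = np.asarray(real_batch, dtype=float)
    fake_batch = np.asarray(fake_batch, dtype=float)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have identical shapes")
    rng = np.random.default_rng(seed)
    eps = rng.uniform(size=(real_batch.shape[0], 1, 1, 1))
    xhat = eps * real_batch + (1.0 - eps) * fake_batch
    gx = _input_gradients(discriminator, xhat, labels)
    norms = np.sqrt(np.sum(gx ** 2, axis=(1, 2, 3)))
    return float(lam * np.mean((norms - 1.0) ** 2))


def _gp_value_and_param_grads(disc: Discriminator, xhat, labels, lam: float):
    """Penalty value and its exact gradient w.r.t. critic parameters.

    d/dtheta of lam*mean((||g_i||-1)^2), with g_i = grad_x D(x_hat_i), equals
    grad_theta of sum_i <g_i, v_i> at fixed v_i = (2 lam / B)(||g_i||-1) g_i/||g_i||.
    That directional derivative of D is evaluated by a central difference in
    input space, which is exact up to rounding for a piecewise-linear critic.
    """
    b = xhat.shape[0]
    gx = _input_gradients(disc, xhat, labels)
    norms = np.sqrt(np.sum(gx ** 2, axis=(1, 2, 3)))
    penalty = float(lam * np.mean((norms - 1.0) ** 2))
    coef = (2.0 * lam / b) * (norms - 1.0) / np.maximum(norms, 1e-12)
    v = coef[:, None, None, None] * gx

    vmax = np.abs(v).max()
    if vmax < 1e-300:
        return penalty, [np.zeros_like(p.grad) for p in disc.params()]
    eps_fd = 1e-6 / vmax

    params = disc.params()
    saved = [p.grad.copy() for p in params]

    def theta_grads(x_in):
        for p in params:
            p.grad[...] = 0.0
        disc.forward(x_in, labels, train=True)
        disc.backward(np.ones((b, 1)))
        return [p.grad.copy() for p in params]

    g_plus = theta_grads(xhat + eps_fd * v)
    g_minus = theta_grads(xhat - eps_fd * v)
    for p, s in zip(params, saved):
        p.grad[...] = s
    return penalty, [(a - c) / (2.0 * eps_fd) for a, c in zip(g_plus, g_minus)]


# ---------------------------------------------------------------------------
# Pre-training
# ---------------------------------------------------------------------------

class _Encoder:
    """Maps spectra to the latent space through the (shared) critic trunk."""

    def __init__(self, disc: Discriminator, latent_dim: int, rng, init_sd=0.02):
        self.trunk = disc.trunk
        self.head = nn.Dense(disc.trunk.flat_dim, latent_dim, rng, init_sd=init_sd)

    def params(self):
        return self.trunk.params() + self.head.params()

    def forward(self, x, train=True):
        return self.head.forward(self.trunk.forward(x, train=train))

    def backward(self, gz):
        return self.trunk.backward(self.head.backward(gz))


def reconstruction_loss(players: PlayerBundle, encoder: _Encoder, grids,
                        label_idx) -> float:
    z = encoder.forward(grids, train=False)
    recon = players.generator.forward(z, label_idx, train=False)
    return float(np.mean((recon - grids) ** 2))


def pretrain(players: PlayerBundle, train_data: SpectralDataset,
             config: ThreePlayerConfig | None = None,
             rng: np.random.Generator | None = None) -> PlayerBundle:
    """Autoencoder initialization: critic trunk encodes, generator decodes.

    Minimizes mean-squared reconstruction of all classes for
    ``pretrain_epochs`` epochs; returns the bundle unchanged when the budget
    is zero.
    """
    config = config or players.config
    if config.pretrain_epochs == 0:
        return players
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    grids = players.to_grid(train_data.values)
    label_idx = players.label_index(train_data.labels)
    encoder = _Encoder(players.discriminator, config.latent_dim, rng,
                       init_sd=config.init_sd)
    opt = nn.Adam(encoder.params() + players.generator.params(),
                  lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    n = grids.shape[0]
    for _epoch in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = grids[idx], label_idx[idx]
            opt.zero_grad()
            z = encoder.forward(x, train=True)
            recon = players.generator.forward(z, y, train=True)
            diff = recon - x
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite reconstruction loss during pretraining")
            gz = players.generator.backward(2.0 * diff / diff.size)
            encoder.backward(gz)
            opt.step()
    # fit the class-conditional latent prior from the trained encoder:
    # per-class means, but a pooled within-class spread.  A minority class
    # with a handful of samples cannot support its own spread estimate; the
    # pooled spread transfers the majority's within-class variation through
    # the shared decoder — the augmentation advantage over interpolating the
    # few minority samples themselves.
    z_all = encoder.forward(grids, train=False)
    centered = np.empty_like(z_all)
    for c in range(len(players.classes)):
        zc = z_all[label_idx == c]
        if len(zc):
            players.generator.latent_mean[c] = zc.mean(axis=0)
            centered[label_idx == c] = zc - zc.mean(axis=0)
    pooled_sd = np.maximum(centered.std(axis=0), 1e-3)
    players.generator.latent_sd[:] = pooled_sd
    if players.ema_generator is not None:
        players.sync_ema()
    return players


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def assemble_balanced_batch(real_grids, real_label_idx, generator: Generator,
                            per_class_target: int, n_classes: int,
                            rng: np.random.Generator, noise_sd: float = 0.0):
    """Fill per-class deficits with generator outputs.

    Returns (grids, label_idx, generated_mask) with exactly
    ``per_class_target`` samples of every class; generated samples are
    flagged in the mask.  ``noise_sd`` adds the estimated measurement noise
    to generated samples (the generator models the class-conditional signal;
    white measurement noise is modeled parametrically on top), clipped back
    to the generator's [-1, 1] range.
    """
    real_label_idx = np.asarray(real_label_idx, dtype=int)
    counts = np.bincount(real_label_idx, minlength=n_classes)
    if per_class_target < counts.max():
        raise ValueError("per_class_target below the largest per-class count")
    deficit_labels = np.concatenate([
        np.full(per_class_target - counts[c], c, dtype=int) for c in range(n_classes)
    ]) if n_classes else np.empty(0, dtype=int)
    if deficit_labels.size == 0:
        return real_grids, real_label_idx, np.zeros(len(real_label_idx), dtype=bool)
    z = generator.sample_latent(deficit_labels, rng)
    fake = generator.forward(z, deficit_labels, train=False)
    if noise_sd > 0:
        fake = np.clip(fake + rng.normal(0.0, noise_sd, size=fake.shape), -1.0, 1.0)
    grids = np.concatenate([real_grids, fake], axis=0)
    labels = np.concatenate([real_label_idx, deficit_labels])
    mask = np.concatenate([np.zeros(len(real_label_idx), dtype=bool),
                           np.ones(deficit_labels.size, dtype=bool)])
    return grids, labels, mask


def critic_step(players: PlayerBundle, real_grids, real_label_idx,
                config: ThreePlayerConfig, rng: np.random.Generator) -> dict:
    """One critic-only update (used for warm-up and inside train_step)."""
    gen, disc = players.generator, players.discriminator
    real_label_idx = np.asarray(real_label_idx, dtype=int)
    b = real_grids.shape[0]
    n_classes = len(players.classes)
    d_loss = penalty = 0.0
    for _ in range(max(config.n_critic, 1)):
        players.opt_d.zero_grad()
        # real-batch labels keep the gradient-penalty interpolates
        # label-consistent between their real and fake endpoints
        fake_labels = real_label_idx
        z = gen.sample_latent(fake_labels, rng)
        fake = gen.forward(z, fake_labels, train=True)
        if players.noise_sd > 0:
            # noise-matched fakes: the critic must judge structure, not
            # smoothness (the noise model is part of the generative model)
            fake = fake + rng.normal(0.0, players.noise_sd, size=fake.shape)
        eps = rng.uniform(size=(b, 1, 1, 1))
        xhat = eps * real_grids + (1.0 - eps) * fake
        penalty, gp_grads = _gp_value_and_param_grads(disc, xhat, real_label_idx,
                                                      config.gp_coefficient)
        ones = np.ones((b, 1))
        real_scores = disc.forward(real_grids, real_label_idx, train=True)
        disc.backward(-ones / b)
        fake_scores = disc.forward(fake, fake_labels, train=True)
        disc.backward(ones / b)
        for p, g in zip(disc.params(), gp_grads):
            p.grad += g
        d_loss = float(fake_scores.mean() - real_scores.mean() + penalty)
        if not np.isfinite(d_loss):
            raise FloatingPointError("non-finite critic loss")
        players.opt_d.step()
    return {"d_loss": d_loss, "gp": float(penalty)}


def balanced_real_batch(grids, label_idx, n_classes: int, batch_size: int,
                        rng: np.random.Generator):
    """Class-balanced draw of real samples (minority resampled with replacement).

    The critic trains against this balanced view of the real data: if it saw
    the raw imbalanced stream, minority-conditioned real samples would be so
    rare that the critic would learn to call the whole minority region
    "fake" and push the generator out of it.
    """
    label_idx = np.asarray(label_idx, dtype=int)
    per_class = max(batch_size // n_classes, 1)
    rows, labels = [], []
    for c in range(n_classes):
        pool = np.flatnonzero(label_idx == c)
        if len(pool) == 0:
            continue
        take = rng.choice(pool, size=per_class, replace=len(pool) < per_class)
        rows.append(grids[take])
        labels.append(np.full(per_class, c, dtype=int))
    return np.concatenate(rows, axis=0), np.concatenate(labels)


def train_step(players: PlayerBundle, real_grids, real_label_idx,
               config: ThreePlayerConfig, rng: np.random.Generator,
               critic_batch=None) -> dict:
    """One three-player iteration: critic, then generator, then classifier.

    1. Critic update on the Wasserstein loss mean D(fake) - mean D(real)
       plus the gradient penalty (``n_critic`` repeats); ``critic_batch``
       optionally supplies a class-balanced real batch for this phase.
    2. Generator update on -mean D(fake) plus ``cooperative_weight`` times
       the classifier cross-entropy of generated samples against their
       conditioning labels, plus critic-trunk feature matching.
    3. Classifier update by cross-entropy on the balanced batch (real +
       generated fill).
    """
    gen, disc, clf = players.generator, players.discriminator, players.classifier
    real_label_idx = np.asarray(real_label_idx, dtype=int)
    b = real_grids.shape[0]
    n_classes = len(players.classes)

    if critic_batch is None:
        critic_batch = (real_grids, real_label_idx)
    critic_rec = critic_step(players, critic_batch[0], critic_batch[1], config, rng)
    d_loss, penalty = critic_rec["d_loss"], critic_rec["gp"]

    # generator: adversarial + cooperative (conditioning labels mirror the
    # balanced real view so minority conditioning trains every step and the
    # feature-matching means are composition-consistent)
    players.opt_g.zero_grad()
    cb_grids, cb_labels = critic_batch
    fake_labels = np.asarray(cb_labels, dtype=int)
    bg = fake_labels.size
    z = gen.sample_latent(fake_labels, rng)
    fake = gen.forward(z, fake_labels, train=True)
    if players.noise_sd > 0:
        fake = fake + rng.normal(0.0, players.noise_sd, size=fake.shape)
    ones = np.ones((bg, 1))
    fake_scores = disc.forward(fake, fake_labels, train=True)
    gx_adv = disc.backward(-ones / bg)
    g_adv = float(-fake_scores.mean())
    logits = clf.forward(fake, train=True)
    g_coop, glogits = nn.cross_entropy(logits, fake_labels)
    gx_coop = clf.backward(config.cooperative_weight * glogits)
    # per-class feature matching against the critic trunk keeps each class's
    # generated samples anchored to that class's real feature statistics
    # (restrains adversarial overshoot past the real data)
    gx_fm = np.zeros_like(fake)
    g_fm = 0.0
    if config.feature_match_weight > 0:
        cb_label_arr = np.asarray(cb_labels, dtype=int)
        feat_real = disc.trunk.forward(cb_grids, train=True)
        feat_fake = disc.trunk.forward(fake, train=True)
        gfeat = np.zeros_like(feat_fake)
        for c in np.unique(fake_labels):
            fm = fake_labels == c
            rm = cb_label_arr == c
            if not rm.any():
                continue
            diff = feat_fake[fm].mean(axis=0) - feat_real[rm].mean(axis=0)
            g_fm += float(np.mean(diff ** 2))
            gfeat[fm] = (2.0 * config.feature_match_weight * diff
                         / diff.size / fm.sum())
        gx_fm = disc.trunk.backward(gfeat)
    gen.backward(gx_adv + gx_coop + gx_fm)
    if not (np.isfinite(g_adv) and np.isfinite(g_coop) and np.isfinite(g_fm)):
        raise FloatingPointError("non-finite generator loss")
    players.opt_g.step()
    players.update_ema(config.ema_decay)

    # classifier: cross-entropy on the balanced batch
    players.opt_c.zero_grad()
    target = int(np.bincount(real_label_idx, minlength=n_classes).max())
    serving_gen = players.ema_generator or gen
    bal_grids, bal_labels, gen_mask = assemble_balanced_batch(
        real_grids, real_label_idx, serving_gen, target, n_classes, rng,
        noise_sd=players.noise_sd)
    logits = clf.forward(bal_grids, train=True)
    c_loss, glogits = nn.cross_entropy(logits, bal_labels)
    clf.backward(glogits)
    if not np.isfinite(c_loss):
        raise FloatingPointError("non-finite classifier loss")
    players.opt_c.step()

    batch_counts = np.bincount(bal_labels, minlength=n_classes)
    return {"d_loss": d_loss, "gp": float(penalty), "g_adv": g_adv,
            "g_coop": float(g_coop), "c_loss": float(c_loss),
            "batch_class_counts": batch_counts.tolist(),
            "n_generated": int(gen_mask.sum())}


def _estimate_noise_sd(train_data: SpectralDataset) -> float:
    """Pooled within-class residual standard deviation (measurement noise)."""
    sq_sum, count = 0.0, 0
    for cls in train_data.classes:
        values = train_data.by_class(cls).values
        if len(values) < 2:
            continue
        resid = values - values.mean(axis=0)
        # unbiased within-class variance, pooled over classes and positions
        sq_sum += float(np.sum(resid ** 2)) * len(values) / (len(values) - 1)
        count += resid.size
    return float(np.sqrt(sq_sum / count)) if count else 0.0


def train(train_data: SpectralDataset, config: ThreePlayerConfig):
    """Full three-player training: pretrain, then ``epochs`` over batches.

    Returns (players, log).  The log carries one record per epoch with the
    averaged losses, the per-class counts of every classifier batch, and the
    classifier's per-class F-scores on the training data.
    """
    if len(train_data.classes) < 2:
        raise ValueError("need at least 2 classes to train")
    players = build_players(config, len(train_data.classes), train_data.length,
                            classes=train_data.classes)
    root = np.random.SeedSequence(config.seed)
    ss_pre, ss_train = root.spawn(2)
    pretrain(players, train_data, config, np.random.default_rng(ss_pre))

    rng = np.random.default_rng(ss_train)
    grids = players.to_grid(train_data.values)
    label_idx = players.label_index(train_data.labels)
    n = grids.shape[0]
    players.noise_sd = _estimate_noise_sd(train_data)
    log = TrainLog()
    n_classes = len(players.classes)
    # critic warm-up: score function near-optimal before the generator moves
    for _epoch in range(config.critic_warmup_epochs):
        for _start in range(0, n, config.batch_size):
            cb = balanced_real_batch(grids, label_idx, n_classes,
                                     config.batch_size, rng)
            critic_step(players, cb[0], cb[1], config, rng)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        step_records = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            cb = balanced_real_batch(grids, label_idx, n_classes,
                                     config.batch_size, rng)
            step_records.append(train_step(players, grids[idx], label_idx[idx],
                                           config, rng, critic_batch=cb))
        record = {"epoch": epoch}
        for key in ("d_loss", "gp", "g_adv", "g_coop", "c_loss"):
            record[key] = float(np.mean([r[key] for r in step_records]))
        record["batch_class_counts"] = [r["batch_class_counts"] for r in step_records]
        probs = predict_proba(players, grids)
        preds = np.argmax(probs, axis=1)
        record["train_per_class_f"] = _per_class_f(label_idx, preds,
                                                   len(players.classes))
        log.records.append(record)
    return players, log


def _per_class_f(true_idx, pred_idx, n_classes) -> list[float]:
    scores = []
    for c in range(n_classes):
        tp = int(np.sum((pred_idx == c) & (true_idx == c)))
        fp = int(np.sum((pred_idx == c) & (true_idx != c)))
        fn = int(np.sum((pred_idx != c) & (true_idx == c)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        scores.append(2 * p * r / (p + r) if p + r else 0.0)
    return scores


def train_classifier(train_data: SpectralDataset, config: ThreePlayerConfig):
    """Train the classifier CNN alone by cross-entropy (no augmentation).

    The reference protocol for the "none" and sampling-based baselines: the
    identical classifier architecture and optimizer, fed whatever training
    set it is given.
    """
    players = build_players(config, len(train_data.classes), train_data.length,
                            classes=train_data.classes)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[-1])
    grids = players.to_grid(train_data.values)
    label_idx = players.label_index(train_data.labels)
    n = grids.shape[0]
    losses = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            players.opt_c.zero_grad()
            logits = players.classifier.forward(grids[idx], train=True)
            loss, glog = nn.cross_entropy(logits, label_idx[idx])
            players.classifier.backward(glog)
            players.opt_c.step()
            epoch_loss.append(loss)
        losses.append(float(np.mean(epoch_loss)))
    return players, losses


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_proba(players: PlayerBundle, grids_or_values) -> np.ndarray:
    x = np.asarray(grids_or_values, dtype=float)
    if x.ndim == 2:
        x = players.to_grid(x)
    return nn.softmax(players.classifier.forward(x, train=False))


def predict_labels(players: PlayerBundle, grids_or_values) -> list[str]:
    """Predicted class labels; exact probability ties break to the lowest index."""
    probs = predict_proba(players, grids_or_values)
    return [players.classes[i] for i in np.argmax(probs, axis=1)]


def generate_minority(players: PlayerBundle, class_label: str, n: int, seed: int,
                      norm: MinMaxNormalizer | None = None,
                      with_noise: bool = False) -> SpectralDataset:
    """Draw ``n`` generated spectra conditioned on ``class_label``.

    Outputs live in the generator's [-1, 1] range unless a normalizer is
    given, in which case they are mapped back to the original scale.  With
    ``with_noise`` the estimated measurement noise is added (as served to
    the classifier during training).  For n = 0 an empty list is returned
    (a dataset cannot hold zero spectra).
    """
    if class_label not in players.classes:
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    gen = players.ema_generator or players.generator
    idx = np.full(n, players.classes.index(class_label), dtype=int)
    z = gen.sample_latent(idx, rng)
    fake = gen.forward(z, idx, train=False)
    if with_noise and players.noise_sd > 0:
        fake = np.clip(fake + rng.normal(0.0, players.noise_sd, size=fake.shape),
                       -1.0, 1.0)
    flat = players.to_flat(fake)
    if norm is not None:
        flat = norm.invert_values(flat)
    spectra = [Spectrum(row, class_label, {"generated": True, "sample": i})
               for i, row in enumerate(flat)]
    return SpectralDataset(spectra, list(players.classes))


def extract_features(players: PlayerBundle, dataset: SpectralDataset) -> np.ndarray:
    """Penultimate classifier activations, one row per spectrum."""
    grids = players.to_grid(dataset.values)
    return players.classifier.features(grids)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def _network_state(net) -> list[np.ndarray]:
    return [p.value for p in net.params()] + list(net.bn_stats())


def make_gan_augmenter(config: ThreePlayerConfig | None = None):
    """An augmenter-registry adapter: train the three-player model on the
    (normalized) training set and append generated spectra up to the target
    counts."""
    def _augment(train_data: SpectralDataset, spec) -> SpectralDataset:
        cfg = config or ThreePlayerConfig.scaled_down()
        cfg = dataclass_replace(cfg, seed=spec.seed)
        players, _log = train(train_data, cfg)
        counts = train_data.class_counts()
        spectra = list(train_data.spectra)
        for cls, target in spec.target_counts.items():
            deficit = target - counts.get(cls, 0)
            if deficit > 0:
                generated = generate_minority(players, cls, deficit,
                                              seed=spec.seed, with_noise=True)
                spectra.extend(generated.spectra)
        return SpectralDataset(spectra, list(train_data.classes))
    return _augment


register_augmenter("threeplayer-gan", make_gan_augmenter())


def save_players(players: PlayerBundle, path) -> None:
    arrays = {}
    for name, net in (("g", players.generator), ("d", players.discriminator),
                      ("c", players.classifier), ("e", players.ema_generator)):
        for i, arr in enumerate(_network_state(net)):
            arrays[f"{name}_{i}"] = arr
    meta = {"config": asdict(players.config), "classes": players.classes,
            "grid": list(players.grid)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_players(path) -> PlayerBundle:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    cfg = meta["config"]
    for key in ("disc_kernels", "gen_kernels", "clf_kernels"):
        cfg[key] = tuple(cfg[key])
    if cfg.get("reshape"):
        cfg["reshape"] = tuple(cfg["reshape"])
    config = ThreePlayerConfig(**cfg)
    players = build_players(config, len(meta["classes"]),
                            meta["grid"][0] * meta["grid"][1],
                            classes=meta["classes"])
    for name, net in (("g", players.generator), ("d", players.discriminator),
                      ("c", players.classifier), ("e", players.ema_generator)):
        state = _network_state(net)
        for i, arr in enumerate(state):
            arr[...] = data[f"{name}_{i}"]
    return players
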