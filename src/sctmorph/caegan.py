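"""Conditional adversarial autoencoder for MR -> synthetic-CT translation.

Four subnetworks share one model: an encoder E mapping the three MR
contrasts (fat, water, R2) to latent statistics (mu, delta); a generator G
decoding a sampled latent z_bar = mu + delta * z back to a CT-like image; a
discriminator D scoring real vs. synthetic patches; and a classifier C that
reuses D's trunk with a softmax head over the three head tissue classes
(soft tissue, air, bone).

E starts with an independent three-convolution stem per contrast (late
fusion by channel concatenation) and E/G form a symmetric encoder-decoder
joined by same-resolution skip concatenations and residual blocks.
Convolutions are Conv-InstanceNorm-ReLU; decoder blocks add dropout
(Deconv realized as nearest-neighbour upsampling + convolution).

The objective is L_total = L_adv + lambda * L_l1 with lambda = 100 by
default: a non-saturating GAN binary cross-entropy plus an auxiliary
3-class cross-entropy on both real and synthetic patches, and a mean
absolute reconstruction error against the reference CT. An optional KL
penalty on (mu, delta) is exposed with weight 0 by default.

Full volumes are synthesized patch-wise (noise disabled, z_bar = mu) and
recombined by averaged overlap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Adam, Conv2d, Dense, InstanceNorm2d, Module
from .volume import Volume, extract_patches, recombine_patches

__all__ = [
    "TrainConfig",
    "CAEGAN",
    "build_model",
    "sample_latent",
    "reconstruction_loss",
    "adversarial_loss",
    "total_loss",
    "train",
    "synthesize",
    "save_model",
    "load_model",
]

_PCLIP = 1e-7


@dataclass
class TrainConfig:
    """Training hyper-parameters; lambda_l1 weights the reconstruction term."""

    lambda_l1: float = 100.0
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    batch_size: int = 8
    steps: int = 200
    seed: int = 0
    dropout: float = 0.5
    kl_weight: float = 0.0

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class ConvBlock(Module):
    """Conv-(InstanceNorm)-(Dropout)-ReLU."""

    def __init__(self, c_in, c_out, stride=1, norm=True, dropout=0.0, rng=None):
        self.conv = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.norm = InstanceNorm2d(c_out) if norm else None
        self.p_drop = dropout

    def __call__(self, x, rng=None, training=False):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        if self.p_drop:
            x = ag.dropout(x, self.p_drop, rng, training)
        return ag.relu(x)


class EncoderResBlock(Module):
    """Conv-IN-ReLU-Conv-IN plus identity, then ReLU."""

    def __init__(self, c, rng=None):
        self.c1 = Conv2d(c, c, 3, rng=rng)
        self.n1 = InstanceNorm2d(c)
        self.c2 = Conv2d(c, c, 3, rng=rng)
        self.n2 = InstanceNorm2d(c)

    def __call__(self, x, rng=None, training=False):
        h = ag.relu(self.n1(self.c1(x)))
        h = self.n2(self.c2(h))
        return ag.relu(h + x)


class DecoderResBlock(Module):
    """Residual block with channel projection and dropout for the decoder."""

    def __init__(self, c_in, c_out, dropout=0.5, rng=None):
        self.c1 = Conv2d(c_in, c_out, 3, rng=rng)
        self.n1 = InstanceNorm2d(c_out)
        self.c2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.n2 = InstanceNorm2d(c_out)
        self.proj = Conv2d(c_in, c_out, 1, padding=0, rng=rng)
        self.p_drop = dropout

    def __call__(self, x, rng=None, training=False):
        h = self.n1(self.c1(x))
        h = ag.dropout(h, self.p_drop, rng, training)
        h = ag.relu(h)
        h = self.n2(self.c2(h))
        return ag.relu(h + self.proj(x))


class Stem(Module):
    """Three Conv-IN-ReLU layers applied to one contrast before fusion."""

    def __init__(self, c_out, rng=None):
        self.blocks = [ConvBlock(1 if i == 0 else c_out, c_out, rng=rng) for i in range(3)]

    def __call__(self, x, rng=None, training=False):
        for b in self.blocks:
            x = b(x)
        return x


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class CAEGAN(Module):
    """Encoder + generator + shared-trunk discriminator/classifier."""

    def __init__(self, n_contrasts=3, base_channels=16, depth=3, dropout=0.5, seed=0):
        if base_channels < 1 or depth < 1:
            raise ValueError("base_channels and depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_contrasts = n_contrasts
        self.base_channels = base_channels
        self.depth = depth
        self.dropout_rate = dropout

        stem_ch = max(4, base_channels // 2)
        chans = [base_channels]
        for _ in range(depth):
            chans.append(min(chans[-1] * 2, base_channels * 4))
        self.chans = chans

        # encoder
        self.stems = [Stem(stem_ch, rng=rng) for _ in range(n_contrasts)]
        self.fuse = ConvBlock(n_contrasts * stem_ch, base_channels, rng=rng)
        self.enc_res = [EncoderResBlock(chans[i], rng=rng) for i in range(depth)]
        self.down = [ConvBlock(chans[i], chans[i + 1], stride=2, rng=rng) for i in range(depth)]
        self.mu_head = Conv2d(chans[-1], chans[-1], 3, rng=rng)
        self.delta_head = Conv2d(chans[-1], chans[-1], 3, rng=rng)

        # generator (decoder)
        self.up = [
            ConvBlock(chans[i + 1], chans[i], dropout=dropout, rng=rng) for i in range(depth - 1, -1, -1)
        ]
        self.dec_res = [
            DecoderResBlock(2 * chans[i], chans[i], dropout=dropout, rng=rng)
            for i in range(depth - 1, -1, -1)
        ]
        self.out_conv = Conv2d(chans[0], 1, 3, rng=rng)

        # discriminator / classifier shared trunk; no normalization on the
        # first block (raw intensity scale is informative) nor on the last
        # (instance norm over a near-singleton spatial extent would erase
        # the features it normalizes)
        d_ch = [base_channels, 2 * base_channels, 4 * base_channels]
        self.d_trunk = [
            ConvBlock(1, d_ch[0], stride=2, norm=False, rng=rng),
            ConvBlock(d_ch[0], d_ch[1], stride=2, rng=rng),
            ConvBlock(d_ch[1], d_ch[2], stride=2, norm=False, rng=rng),
        ]
        self.d_head = Dense(d_ch[2], 1, rng=rng)
        self.c_head = Dense(d_ch[2], 3, rng=rng)

    # -- sub-network parameter groups ------------------------------------
    def generator_parameters(self):
        mods = [*self.stems, self.fuse, *self.enc_res, *self.down, self.mu_head, self.delta_head,
                *self.up, *self.dec_res, self.out_conv]
        out = []
        for m in mods:
            out.extend(m.parameters())
        return out

    def discriminator_parameters(self):
        out = []
        for m in [*self.d_trunk, self.d_head, self.c_head]:
            out.extend(m.parameters())
        return out

    # -- forward passes ---------------------------------------------------
    def encode(self, contrasts, rng=None, training=False):
        """contrasts: list of (N,1,H,W) tensors -> (mu, delta, skips)."""
        if len(contrasts) != self.n_contrasts:
            raise ValueError(f"expected {self.n_contrasts} contrasts, got {len(contrasts)}")
        feats = [stem(x, rng, training) for stem, x in zip(self.stems, contrasts)]
        h = self.fuse(ag.concat(feats, axis=1), rng, training)
        skips = []
        for res, down in zip(self.enc_res, self.down):
            h = res(h, rng, training)
            skips.append(h)
            h = down(h, rng, training)
        mu = self.mu_head(h)
        delta = ag.softplus(self.delta_head(h))
        return mu, delta, skips

    def generate(self, z_bar, skips, rng=None, training=False):
        h = z_bar
        for up, res, skip in zip(self.up, self.dec_res, reversed(skips)):
            h = up(ag.upsample2(h), rng, training)
            h = res(ag.concat([h, skip], axis=1), rng, training)
        return self.out_conv(h)

    def discriminate(self, y, rng=None, training=False):
        """Image -> (real/fake probability (N,), class probabilities (N,3))."""
        h = y
        for blk in self.d_trunk:
            h = blk(h, rng, training)
        feat = ag.global_avg_pool(h)
        d = ag.sigmoid(self.d_head(feat)).reshape(-1)
        c = ag.softmax(self.c_head(feat), axis=1)
        return d, c

    def forward_synthesis(self, contrasts, z=None, rng=None, training=False):
        """Full E -> sample -> G pass. z=None disables noise (z_bar = mu)."""
        mu, delta, skips = self.encode(contrasts, rng, training)
        z_bar = mu if z is None else sample_latent(mu, delta, z)
        y_hat = self.generate(z_bar, skips, rng, training)
        return y_hat, mu, delta


def build_model(dim: int = 2, n_contrasts: int = 3, base_channels: int = 16, depth: int = 3,
                dropout: float = 0.5, seed: int = 0) -> CAEGAN:
    """Construct the synthesis model (2D; patch sides must be divisible by 2**depth)."""
    if dim != 2:
        raise ValueError("the synthesis model is 2D; register/warp handle 3D volumes slice-wise if needed")
    return CAEGAN(n_contrasts=n_contrasts, base_channels=base_channels, depth=depth,
                  dropout=dropout, seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def sample_latent(mu, delta, z):
    """z_bar = mu + delta * z, elementwise; works on tensors or arrays."""
    if isinstance(mu, Tensor) or isinstance(delta, Tensor):
        z_t = z if isinstance(z, Tensor) else Tensor(z)
        return mu + delta * z_t
    mu, delta, z = (np.asarray(a, dtype=np.float64) for a in (mu, delta, z))
    if mu.shape != delta.shape or mu.shape != z.shape:
        raise ValueError("mu, delta and z shapes must match")
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    return mu + delta * z


def reconstruction_loss(y, y_hat):
    """Mean absolute (L1) difference between reference and synthetic image."""
    if isinstance(y, Tensor) or isinstance(y_hat, Tensor):
        return ag.mean(ag.absolute(y_hat - y))
    ya = y.data if isinstance(y, Volume) else np.asarray(y, dtype=np.float64)
    yh = y_hat.data if isinstance(y_hat, Volume) else np.asarray(y_hat, dtype=np.float64)
    if ya.shape != yh.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(ya - yh)))


def _ce_tensor(c_prob: Tensor, labels) -> Tensor:
    picked = ag.gather_rows(ag.clip(c_prob, _PCLIP, 1.0 - _PCLIP), labels)
    return -1.0 * ag.mean(ag.log(picked))


def adversarial_loss(d_real, d_fake, c_real, c_fake, labels):
    """Non-saturating GAN BCE plus auxiliary 3-class cross-entropy.

    D maximizes log d_real + log(1 - d_fake); G minimizes -log d_fake
    (non-saturating variant). The classifier terms penalize both the real
    and the synthetic stream against the patch tissue labels. Returns
    ``(loss_D, loss_G)``.
    """
    if isinstance(d_real, Tensor):
        dr = ag.clip(d_real, _PCLIP, 1.0 - _PCLIP)
        df = ag.clip(d_fake, _PCLIP, 1.0 - _PCLIP)
        ce_r = _ce_tensor(c_real, labels)
        ce_f = _ce_tensor(c_fake, labels)
        loss_d = -1.0 * ag.mean(ag.log(dr)) - 1.0 * ag.mean(ag.log(1.0 - df)) + ce_r + ce_f
        loss_g = -1.0 * ag.mean(ag.log(df)) + ce_f
        return loss_d, loss_g
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _PCLIP, 1 - _PCLIP)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _PCLIP, 1 - _PCLIP)
    labels = np.asarray(labels, dtype=np.int64)
    rows = np.arange(len(labels))
    cr = np.clip(np.asarray(c_real, dtype=np.float64)[rows, labels], _PCLIP, 1.0)
    cf = np.clip(np.asarray(c_fake, dtype=np.float64)[rows, labels], _PCLIP, 1.0)
    loss_d = float(-np.mean(np.log(dr)) - np.mean(np.log(1 - df)) - np.mean(np.log(cr)) - np.mean(np.log(cf)))
    loss_g = float(-np.mean(np.log(df)) - np.mean(np.log(cf)))
    return loss_d, loss_g


def total_loss(loss_adv, loss_l1, lambda_l1: float = 100.0):
    """L_total = L_adv + lambda * L_l1."""
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be >= 0")
    return loss_adv + lambda_l1 * loss_l1


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _to_contrast_tensors(xb: np.ndarray):
    # (N, n_contrasts, H, W) -> list of (N,1,H,W) tensors
    return [Tensor(xb[:, i : i + 1]) for i in range(xb.shape[1])]


def train(model: CAEGAN, dataset, config: TrainConfig | None = None):
    """Alternating D/C and E+G updates on paired patches.

    ``dataset`` is a sequence of ``(x, y, label)`` with x of shape
    (n_contrasts, H, W), y of shape (H, W) and an integer tissue label
    following the phantom convention (0 air, 1 soft tissue, 2 bone).
    Deterministic given ``config.seed``. Returns the per-step loss history.
    """
    config = config or TrainConfig()
    data = list(dataset)
    if not data:
        raise ValueError("empty training dataset")
    xs = np.stack([np.asarray(d[0], dtype=np.float64) for d in data])
    ys = np.stack([np.asarray(d[1], dtype=np.float64) for d in data])
    labels = np.asarray([int(d[2]) for d in data])
    rng = np.random.default_rng(config.seed)
    opt_g = Adam(model.generator_parameters(), lr=config.lr_g)
    opt_d = Adam(model.discriminator_parameters(), lr=config.lr_d)
    history = []

    for step in range(config.steps):
        idx = rng.choice(len(data), size=min(config.batch_size, len(data)), replace=False)
        contrasts = _to_contrast_tensors(xs[idx])
        yb = Tensor(ys[idx][:, None])
        lb = labels[idx]
        z = rng.standard_normal(
            (len(idx), model.chans[-1]) + tuple(s // 2**model.depth for s in ys.shape[1:])
        )

        y_hat, mu, delta = model.forward_synthesis(contrasts, z=z, rng=rng, training=True)

        # --- D/C step on detached fakes
        opt_d.zero_grad()
        d_real, c_real = model.discriminate(yb, rng=rng, training=True)
        d_fake, c_fake = model.discriminate(y_hat.detach(), rng=rng, training=True)
        loss_d, _ = adversarial_loss(d_real, d_fake, c_real, c_fake, lb)
        loss_d.backward()
        opt_d.step()

        # --- E+G step through the live graph
        opt_g.zero_grad()
        d_fake2, c_fake2 = model.discriminate(y_hat, rng=rng, training=True)
        _, loss_g_adv = adversarial_loss(d_real.detach(), d_fake2, c_real.detach(), c_fake2, lb)
        loss_l1 = reconstruction_loss(yb, y_hat)
        loss_total = total_loss(loss_g_adv, loss_l1, config.lambda_l1)
        if config.kl_weight > 0:
            kl = ag.mean(0.5 * (mu * mu + delta * delta - 2.0 * ag.log(delta + 1e-8) - 1.0))
            loss_total = loss_total + config.kl_weight * kl
        loss_total.backward()
        opt_g.step()

        acc = float(np.mean(np.argmax(c_real.data, axis=1) == lb))
        rec = {
            "step": step,
            "loss_d": loss_d.item(),
            "loss_g_adv": loss_g_adv.item(),
            "loss_l1": loss_l1.item(),
            "loss_total": loss_total.item(),
            "class_acc": acc,
        }
        if not all(np.isfinite(v) for k, v in rec.items() if k != "step"):
            raise RuntimeError(f"non-finite loss at step {step}: {rec}")
        history.append(rec)
    return history


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def synthesize(model: CAEGAN, contrasts, patch_shape=16, stride=8, batch: int = 16) -> Volume:
    """Patch-wise synthetic-CT inference, noise disabled (z_bar = mu).

    ``contrasts`` is a sequence of co-registered Volumes (or arrays), one
    per MR contrast; patches slide with clamped boundaries and overlaps are
    averaged on recombination.
    """
    vols = [c if isinstance(c, Volume) else Volume(c) for c in contrasts]
    if len(vols) != model.n_contrasts:
        raise ValueError(f"expected {model.n_contrasts} contrasts, got {len(vols)}")
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError("contrast shapes differ")
    patch_lists = [extract_patches(v, patch_shape, stride) for v in vols]
    offsets = [off for off, _ in patch_lists[0]]
    n = len(offsets)
    out_patches = []
    for start in range(0, n, batch):
        sel = slice(start, min(start + batch, n))
        xb = np.stack(
            [
                np.stack([plist[i][1].data for plist in patch_lists])
                for i in range(sel.start, sel.stop)
            ]
        )  # (b, n_contrasts, H, W)
        tensors = _to_contrast_tensors(xb)
        y_hat, _, _ = model.forward_synthesis(tensors, z=None, rng=None, training=False)
        for j, i in enumerate(range(sel.start, sel.stop)):
            out_patches.append((offsets[i], y_hat.data[j, 0]))
    out = recombine_patches(out_patches, shape, spacing=vols[0].spacing, origin=vols[0].origin)
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: CAEGAN, path, train_config: TrainConfig | None = None) -> None:
    """Single-file checkpoint: weights + architecture + training config."""
    meta = {
        "n_contrasts": model.n_contrasts,
        "base_channels": model.base_channels,
        "depth": model.depth,
        "dropout": model.dropout_rate,
        "train_config": asdict(train_config) if train_config else None,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(str(path), meta=json.dumps(meta), **arrays)


def load_model(path) -> CAEGAN:
    with np.load(str(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
    model = CAEGAN(
        n_contrasts=meta["n_contrasts"],
        base_channels=meta["base_channels"],
        depth=meta["depth"],
        dropout=meta["dropout"],
    )
    model.load_state_arrays(arrays)
    return model
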