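"""Spatial VAE for probabilistic label maps.

The first stage of the label generator: a convolutional VAE whose latent is
a spatial grid (not a flat vector), so a diffusion model can later operate
on it.  The 2D configuration uses two downsamplings and a 3-channel latent;
the 3D configuration three downsamplings and an 8-channel latent, keeping
the compression ratios of the reference design while scaling with input
size.

Training minimises a five-term loss: KL divergence of the posterior against
N(0,1); a perceptual loss through a pluggable feature extractor; a
patch-GAN adversarial loss; a focal reconstruction loss; and a
noise-robustness loss that reconstructs from a perturbed latent
(z + eps, eps ~ N(0, sigma^2), sigma = 0.05 by default) so that small latent
displacements — like the ones a diffusion sampler will produce — still
decode to clean labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .types import LabelMapError, ProbLabelMap, renormalise_probabilities

_EPS = 1e-6


@dataclass
class LatentGrid:
    """Posterior over a spatial latent: mean/logvar grids plus a sample."""

    mean: np.ndarray
    logvar: np.ndarray
    z: np.ndarray
    downsampling: int

    def __post_init__(self):
        if self.mean.shape != self.logvar.shape or self.mean.shape != self.z.shape:
            raise ValueError("inconsistent latent grid shapes")
        if not (np.isfinite(self.mean).all() and np.isfinite(self.logvar).all()):
            raise ValueError("non-finite latent grid")


@dataclass
class VaeLossWeights:
    """Weights of the five VAE loss terms plus the focal / noise settings.

    Defaults put all terms within roughly one order of magnitude on phantom
    batches at initialisation.
    """

    kld: float = 1e-4
    perceptual: float = 0.3
    adversarial: float = 0.05
    focal: float = 1.0
    noise_robust: float = 1.0
    focal_gamma: float = 0.3
    focal_alpha: float = 0.9
    noise_mu: float = 0.0
    noise_sigma: float = 0.05

    def validate(self) -> None:
        for name in ("kld", "perceptual", "adversarial", "focal", "noise_robust"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative loss weight {name}")
        if self.focal_gamma <= 0:
            raise ValueError("focal gamma must be > 0")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def focal_recon_loss(l, l_hat, gamma: float = 0.3, alpha: float = 0.9) -> Tensor:
    """Focal reconstruction loss between target probabilities and decoded ones.

    Per element, the binary KL divergence KL(l || l_hat) — the cross-entropy
    with the target's own entropy subtracted, so a perfect reconstruction
    scores exactly zero even on fractional boundary probabilities — weighted
    by the focal factor |l - l_hat|^gamma that concentrates on badly
    reconstructed pixels, and by the class-balance factor
    alpha*l + (1-alpha)*(1-l) that keeps rare foreground voxels (small
    lesions occupy a few percent of a slice) from being drowned out by
    background.  Mean reduction over channels and pixels.
    """
    l = l if isinstance(l, Tensor) else Tensor(np.asarray(l, dtype=np.float64))
    l_hat = l_hat if isinstance(l_hat, Tensor) else Tensor(np.asarray(l_hat, dtype=np.float64))
    if l.shape != l_hat.shape:
        raise LabelMapError("shape mismatch in focal loss")
    if not np.isfinite(l.data).all() or not np.isfinite(l_hat.data).all():
        raise LabelMapError("non-finite input to focal loss")
    p = l_hat.clip(_EPS, 1.0 - _EPS)
    t = np.clip(l.data, _EPS, 1.0 - _EPS)
    # KL(t || p), target side constant
    ce = -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log())
    ent = -(t * np.log(t) + (1.0 - t) * np.log(1.0 - t))
    kl = ce - Tensor(ent)
    w = (((l_hat - l) * (l_hat - l)) + _EPS**2) ** (gamma / 2.0)  # |l-lhat|^gamma, smoothed
    a = alpha * t + (1.0 - alpha) * (1.0 - t)
    return (w * Tensor(2.0 * a) * kl).mean()


def gaussian_kld(mean, logvar, reduction: str = "mean") -> Tensor:
    """KL( N(mean, exp(logvar)) || N(0, 1) ), elementwise
    0.5 * (mean^2 + var - logvar - 1); ``reduction`` is "mean" or "sum"."""
    mean = mean if isinstance(mean, Tensor) else Tensor(mean)
    logvar = logvar if isinstance(logvar, Tensor) else Tensor(logvar)
    term = (mean * mean + logvar.exp() - logvar - 1.0) * 0.5
    return term.mean() if reduction == "mean" else term.sum()


class RandomFeatureExtractor(nn.Module):
    """Fixed-seed untrained convolutional feature stack used as the default
    perceptual-loss backbone; any module with the same ``features`` contract
    (list of feature tensors) can be plugged in instead."""

    def __init__(self, cin: int, ndim: int = 2, width: int = 8, seed: int = 1234):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv(cin, width, 3, 2, 1, ndim=ndim, rng=rng)
        self.c2 = nn.Conv(width, width * 2, 3, 2, 1, ndim=ndim, rng=rng)

    def features(self, x: Tensor) -> list[Tensor]:
        f1 = self.c1(x).leaky_relu(0.2)
        f2 = self.c2(f1).leaky_relu(0.2)
        return [f1, f2]


def perceptual_loss(x, y, extractor) -> Tensor:
    """Sum of L1 distances between extractor feature maps of x and y."""
    fx = extractor.features(x if isinstance(x, Tensor) else Tensor(x))
    fy = extractor.features(y if isinstance(y, Tensor) else Tensor(y))
    total = None
    for a, b in zip(fx, fy):
        term = (a - b).abs().mean()
        total = term if total is None else total + term
    return total


class PatchDiscriminator(nn.Module):
    """Patch-GAN discriminator over label maps: per-patch real/fake scores
    plus intermediate feature maps."""

    def __init__(self, cin: int, width: int = 16, ndim: int = 2, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv(cin, width, 3, 2, 1, ndim=ndim, rng=rng)
        self.c2 = nn.Conv(width, width * 2, 3, 2, 1, ndim=ndim, rng=rng)
        self.c3 = nn.Conv(width * 2, 1, 3, 1, 1, ndim=ndim, rng=rng)

    def forward(self, x: Tensor):
        f1 = self.c1(x).leaky_relu(0.2)
        f2 = self.c2(f1).leaky_relu(0.2)
        scores = self.c3(f2)
        return scores, [f1, f2]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class VaeConfig:
    channels: int = 9
    width: int = 24
    latent_channels: int = 3  # 8 for 3D
    n_downsamplings: int = 2  # 3 for 3D
    ndim: int = 2
    seed: int = 0


class LabelVAE(nn.Module):
    """Spatial VAE over probabilistic label maps."""

    def __init__(self, config: VaeConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, w, zc, nd = config.channels, config.width, config.latent_channels, config.ndim
        # downsample immediately: all heavy convolutions run at reduced
        # resolution, only the first/last layer touch the full grid
        downs = []
        cur_in, cur = c, w
        for _ in range(config.n_downsamplings):
            downs += [nn.Conv(cur_in, cur, 3, 2, 1, ndim=nd, rng=rng), nn.LeakyReLU()]
            cur_in, cur = cur, cur * 2
        downs += [
            nn.Conv(cur_in, cur_in, 3, 1, 1, ndim=nd, rng=rng), nn.LeakyReLU(),
            nn.Conv(cur_in, cur_in, 3, 1, 1, ndim=nd, rng=rng), nn.LeakyReLU(),
        ]
        self.encoder = nn.Sequential(*downs)
        self.to_stats = nn.Conv(cur_in, 2 * zc, 3, 1, 1, ndim=nd, rng=rng)
        ups = [
            nn.Conv(zc, cur_in, 3, 1, 1, ndim=nd, rng=rng), nn.LeakyReLU(),
            nn.Conv(cur_in, cur_in, 3, 1, 1, ndim=nd, rng=rng), nn.LeakyReLU(),
        ]
        cur = cur_in
        for i in range(config.n_downsamplings):
            cout = max(w, cur // 2)
            ups += [nn.Upsample(2), nn.Conv(cur, cout, 3, 1, 1, ndim=nd, rng=rng), nn.LeakyReLU()]
            cur = cout
        # full-resolution refinement: sharpens small structures that a
        # single post-upsample convolution leaves blurred
        ups += [nn.Conv(cur, c, 3, 1, 1, ndim=nd, rng=rng)]
        self.decoder = nn.Sequential(*ups)

    # -- operations ------------------------------------------------------
    def _check_shape(self, spatial):
        f = 2 ** self.config.n_downsamplings
        bad = [s for s in spatial if s % f]
        if bad:
            raise LabelMapError(
                f"spatial dims {spatial} not divisible by {f}; pad to a multiple of {f}"
            )

    def encode_tensor(self, x: Tensor):
        self._check_shape(x.shape[2:])
        h = self.encoder(x)
        stats = self.to_stats(h)
        zc = self.config.latent_channels
        mean = stats[:, :zc]
        logvar = stats[:, zc:].clip(-10.0, 10.0)
        return mean, logvar

    def encode(self, label: ProbLabelMap, rng_seed: int = 0) -> LatentGrid:
        """Encode one label map; the sample z uses the reparameterisation
        z = mean + exp(logvar/2) * eps.  In eval mode z equals the mean."""
        x = Tensor(label.array[None].astype(np.float32))
        mean, logvar = self.encode_tensor(x)
        m, lv = mean.data[0], logvar.data[0]
        if self.training:
            eps = np.random.default_rng(rng_seed).standard_normal(m.shape).astype(np.float32)
            z = m + np.exp(lv / 2.0) * eps
        else:
            z = m.copy()
        return LatentGrid(mean=m, logvar=lv, z=z, downsampling=2 ** self.config.n_downsamplings)

    def decode_tensor(self, z: Tensor) -> Tensor:
        if z.shape[1] != self.config.latent_channels:
            raise LabelMapError("latent channel mismatch")
        return self.decoder(z).sigmoid()

    def decode(self, z: LatentGrid | np.ndarray) -> ProbLabelMap:
        """Decode a latent to a label map; channel sums are renormalised to
        restore the per-voxel sum <= 1 invariant."""
        arr = z.z if isinstance(z, LatentGrid) else np.asarray(z, dtype=np.float32)
        out = self.decode_tensor(Tensor(arr[None].astype(np.float32))).data[0]
        return ProbLabelMap(array=renormalise_probabilities(out))


def noise_robust_loss(
    model: LabelVAE, l: Tensor, z: Tensor, sigma: float, rng_seed: int,
    gamma: float = 0.3, alpha: float = 0.9, mu: float = 0.0,
) -> Tensor:
    """Focal loss between l and decode(z + eps), eps ~ N(mu, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    eps = np.random.default_rng(rng_seed).normal(mu, sigma, size=z.shape) if sigma > 0 else 0.0
    z_pert = z + Tensor(np.asarray(eps, dtype=np.float32)) if sigma > 0 else z
    return focal_recon_loss(l, model.decode_tensor(z_pert), gamma, alpha)


def vae_total_loss(
    model: LabelVAE,
    l: Tensor,
    weights: VaeLossWeights,
    feature_extractor,
    discriminator: PatchDiscriminator | None,
    rng_seed: int = 0,
):
    """Five-term VAE loss; returns (total, breakdown dict of Tensors).

    The breakdown entries are the *weighted* terms and sum to the total.
    """
    weights.validate()
    mean, logvar = model.encode_tensor(l)
    rng = np.random.default_rng(rng_seed)
    eps = Tensor(rng.standard_normal(mean.shape).astype(np.float32))
    z = mean + (logvar * 0.5).exp() * eps
    l_hat = model.decode_tensor(z)

    terms: dict[str, Tensor] = {}
    terms["kld"] = gaussian_kld(mean, logvar, reduction="mean") * weights.kld
    terms["focal"] = focal_recon_loss(l, l_hat, weights.focal_gamma, weights.focal_alpha) * weights.focal
    terms["noise_robust"] = (
        noise_robust_loss(
            model, l, z, weights.noise_sigma, int(rng.integers(0, 2**31 - 1)),
            weights.focal_gamma, weights.focal_alpha, weights.noise_mu,
        )
        * weights.noise_robust
    )
    if weights.perceptual > 0 and feature_extractor is not None:
        terms["perceptual"] = perceptual_loss(l, l_hat, feature_extractor) * weights.perceptual
    else:
        terms["perceptual"] = Tensor(np.float64(0.0))
    if weights.adversarial > 0 and discriminator is not None:
        fake_scores, _ = discriminator(l_hat)
        terms["adversarial"] = -fake_scores.mean() * weights.adversarial
    else:
        terms["adversarial"] = Tensor(np.float64(0.0))

    total = None
    for t in terms.values():
        total = t if total is None else total + t
    return total, terms


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class VaeTrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 2e-3
    disc_lr: float = 1e-3
    seed: int = 0
    weights: VaeLossWeights = field(default_factory=VaeLossWeights)
    model: VaeConfig = field(default_factory=VaeConfig)


def train_label_vae(dataset: list[ProbLabelMap], config: VaeTrainConfig):
    """Train the S-VAE with its patch discriminator.

    Returns ``(model, history)`` where history is a list of per-epoch mean
    loss breakdowns.  Fully deterministic under ``config.seed``.
    """
    if not dataset:
        raise LabelMapError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    model = LabelVAE(config.model)
    disc = PatchDiscriminator(config.model.channels, ndim=config.model.ndim, seed=config.seed + 1)
    extractor = RandomFeatureExtractor(config.model.channels, ndim=config.model.ndim)
    opt_g = nn.Adam(model.parameters(), lr=config.lr)
    opt_d = nn.Adam(disc.parameters(), lr=config.disc_lr)
    data = np.stack([lab.array for lab in dataset]).astype(np.float32)
    n = len(data)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        nb = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = Tensor(data[idx])
            step_seed = int(rng.integers(0, 2**31 - 1))
            total, terms = vae_total_loss(
                model, batch, config.weights, extractor, disc, rng_seed=step_seed
            )
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"VAE training diverged (epoch {epoch}): "
                    + {k: v.item() for k, v in terms.items()}.__repr__()
                )
            opt_g.zero_grad()
            total.backward()
            opt_g.step()
            # discriminator: hinge on real vs reconstructed (detached),
            # updated every other generator step
            if config.weights.adversarial > 0 and nb % 2 == 0:
                from .nn.tensor import no_grad

                with no_grad():
                    mean, _ = model.encode_tensor(batch)
                    fake = model.decode_tensor(mean).detach()
                sr, _ = disc(batch)
                sf, _ = disc(fake)
                d_loss = (1.0 - sr).relu().mean() + (1.0 + sf).relu().mean()
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
            for k, v in terms.items():
                sums[k] = sums.get(k, 0.0) + v.item()
            sums["total"] = sums.get("total", 0.0) + total.item()
            nb += 1
        history.append({k: v / nb for k, v in sums.items()})
    model.eval()
    return model, history


def reconstruction_mae(model: LabelVAE, dataset: list[ProbLabelMap]) -> float:
    """Mean per-channel absolute reconstruction error over a dataset
    (eval mode: z = posterior mean)."""
    model.eval()
    errs = []
    for lab in dataset:
        z = model.encode(lab)
        rec = model.decode(z)
        errs.append(np.abs(rec.array - lab.array).mean())
    return float(np.mean(errs))
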