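"""Semantic image generator: a style/content-separated VAE-GAN.

A style encoder compresses an intensity image into a 16-dimensional style
code (the MRI contrast: modality and scanner flavour); a decoder driven by
spatially-adaptive normalisation (per-pixel scale/shift predicted from the
probabilistic semantic map at every decoder resolution) renders the
anatomy in that style.  Training combines a multi-scale patch-GAN hinge
loss, feature matching, a perceptual loss, the style KLD, and a
contrastive style loss on affine-augmented pairs; style and content are
further disentangled by drawing the style image from a *different* slice
of the same volume as the ground-truth image.  An adversarial scheduler
gates generator/discriminator updates by windowed discriminator accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .nn.tensor import avg_pool, no_grad
from .types import LabelMapError, ProbLabelMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# style code
# ---------------------------------------------------------------------------

@dataclass
class StyleCode:
    """Compact latent style representation of an intensity image."""

    mean: np.ndarray
    logvar: np.ndarray
    s: np.ndarray
    modality: str = ""
    dataset_tag: str = ""

    def __post_init__(self):
        if not np.isfinite(self.s).all():
            raise ValueError("non-finite style code")


# ---------------------------------------------------------------------------
# scheduler
# ---------------------------------------------------------------------------

@dataclass
class SchedulerState:
    """Rolling window of discriminator accuracies with the two gating
    thresholds: above ``t_up`` only the generator trains, below ``t_down``
    only the discriminator, in between both (strict inequalities)."""

    window: list[float] = field(default_factory=list)
    window_size: int = 20
    t_up: float = 0.75
    t_down: float = 0.6

    def __post_init__(self):
        if not self.t_down < self.t_up:
            raise ValueError("t_down must be < t_up")


def scheduler_step(state: SchedulerState, new_d_accuracy: float):
    """Update the accuracy window and decide which networks train.

    Returns ``(train_G, train_D, state)``.  A window shorter than
    ``window_size`` uses the entries available.
    """
    if not 0.0 <= new_d_accuracy <= 1.0:
        raise ValueError("discriminator accuracy must lie in [0, 1]")
    state.window.append(float(new_d_accuracy))
    if len(state.window) > state.window_size:
        state.window = state.window[-state.window_size :]
    mean_acc = float(np.mean(state.window))
    # strict inequalities with a float-accumulation guard: a window mean at
    # exactly a threshold trains both networks
    eps = 1e-9
    if mean_acc > state.t_up + eps:
        return True, False, state
    if mean_acc < state.t_down - eps:
        return False, True, state
    return True, True, state


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def hinge_gan_loss(scores_real, scores_fake, side: str) -> Tensor:
    """Hinge GAN loss summed over discriminator scales.

    ``side="discriminator"``: mean(relu(1 - real)) + mean(relu(1 + fake));
    ``side="generator"``: -mean(fake).  Scores may be single tensors or
    lists (one per scale).
    """
    reals = scores_real if isinstance(scores_real, (list, tuple)) else [scores_real]
    fakes = scores_fake if isinstance(scores_fake, (list, tuple)) else [scores_fake]
    total = None
    if side == "discriminator":
        for r, f in zip(reals, fakes):
            if r.shape != f.shape:
                raise ValueError("real/fake score shape mismatch")
            term = (1.0 - r).relu().mean() + (1.0 + f).relu().mean()
            total = term if total is None else total + term
    elif side == "generator":
        for f in fakes:
            term = -f.mean()
            total = term if total is None else total + term
    else:
        raise ValueError(f"unknown side {side!r}")
    return total


def feature_matching_loss(features_real, features_fake) -> Tensor:
    """Sum over scales and layers of L1 distances between discriminator
    feature maps for real and synthetic inputs (real side detached)."""
    if len(features_real) != len(features_fake):
        raise ValueError("mismatched scale counts")
    total = None
    for fr_list, ff_list in zip(features_real, features_fake):
        if len(fr_list) != len(ff_list):
            raise ValueError("mismatched feature counts within a scale")
        for fr, ff in zip(fr_list, ff_list):
            term = (ff - fr.detach()).abs().mean()
            total = term if total is None else total + term
    return total


def perceptual_loss(i, i_tilde, feature_extractor) -> Tensor:
    """Sum of L1 distances between extractor feature maps (pluggable
    backbone; the default is the fixed-seed random stack)."""
    from .autoencoder import perceptual_loss as _pl

    return _pl(i, i_tilde, feature_extractor)


def cosine_similarity(a: Tensor, b: Tensor) -> Tensor:
    """Batched cosine similarity over the last axis; mean over the batch."""
    na = ((a * a).sum(axis=-1) + 1e-12).sqrt()
    nb = ((b * b).sum(axis=-1) + 1e-12).sqrt()
    if float(na.data.min()) < 1e-5 or float(nb.data.min()) < 1e-5:
        raise ValueError("zero-norm style code in cosine similarity")
    return ((a * b).sum(axis=-1) / (na * nb)).mean()


def random_affine(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Contrast-preserving geometric augmentation: rotation <= 10 degrees,
    translation <= 5%, isotropic scale in [0.95, 1.05]."""
    ang = np.deg2rad(rng.uniform(-10, 10))
    sc = rng.uniform(0.95, 1.05)
    c, s = np.cos(ang) / sc, np.sin(ang) / sc
    mat = np.array([[c, -s], [s, c]])
    centre = (np.array(img.shape) - 1) / 2.0
    shift = rng.uniform(-0.05, 0.05, size=2) * np.array(img.shape)
    offset = centre - mat @ centre + shift
    return ndimage.affine_transform(img, mat, offset=offset, order=1, mode="nearest").astype(
        np.float32
    )


def contrastive_style_loss(encoder, images: np.ndarray, augmenter, rng_seed: int) -> Tensor:
    """1 - cosine similarity between style codes of images and their
    randomly affine-augmented versions (minimised, so the encoder is pushed
    to see contrast, not geometry)."""
    rng = np.random.default_rng(rng_seed)
    aug = np.stack([augmenter(im, rng) for im in images])
    m1, _ = encoder.stats(Tensor(images[:, None].astype(np.float32)))
    m2, _ = encoder.stats(Tensor(aug[:, None].astype(np.float32)))
    return 1.0 - cosine_similarity(m1, m2)


def modality_dataset_disc_loss(
    classifier, images: np.ndarray, modality_onehot: np.ndarray, dataset_onehot: np.ndarray,
    lambda_mod: float, lambda_dat: float,
) -> Tensor:
    """Auxiliary modality/dataset discrimination loss (binary cross-entropy
    against a pretrained classifier's predictions).  Off by default: the
    ablation study found it did not improve slice consistency."""
    if lambda_mod == 0 and lambda_dat == 0:
        return Tensor(np.float64(0.0))
    if classifier is None:
        raise ValueError("auxiliary classifier required when mod/dat loss enabled")
    pm, pd = classifier(Tensor(images[:, None].astype(np.float32)))

    def bce(pred: Tensor, target: np.ndarray) -> Tensor:
        p = pred.sigmoid().clip(1e-6, 1 - 1e-6)
        t = Tensor(target.astype(np.float32))
        return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()

    return bce(pm, modality_onehot) * lambda_mod + bce(pd, dataset_onehot) * lambda_dat


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class ImageGenConfig:
    label_channels: int = 9
    style_dim: int = 16
    width: int = 24
    image_size: int = 32
    modalities: tuple[str, ...] = ("T1", "FLAIR")
    n_disc_scales: int = 2
    seed: int = 0


class StyleEncoder(nn.Module):
    """Image -> 16-dim style posterior (mean, logvar)."""

    def __init__(self, cfg: ImageGenConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        w = cfg.width
        self.c1 = nn.Conv(1, w, 3, 2, 1, rng=rng)
        self.c2 = nn.Conv(w, w * 2, 3, 2, 1, rng=rng)
        self.c3 = nn.Conv(w * 2, w * 2, 3, 2, 1, rng=rng)
        self.fc = nn.Linear(w * 2, 2 * cfg.style_dim, rng=rng)
        self.style_dim = cfg.style_dim

    def stats(self, x: Tensor):
        h = self.c1(x).leaky_relu(0.2)
        h = self.c2(h).leaky_relu(0.2)
        h = self.c3(h).leaky_relu(0.2)
        pooled = h.mean(axis=(2, 3))
        out = self.fc(pooled)
        return out[:, : self.style_dim], out[:, self.style_dim :].clip(-10.0, 10.0)


class SpadeBlock(nn.Module):
    """Spatially-adaptive normalisation: the semantic map, pooled to the
    feature resolution, predicts per-pixel scale and shift applied to the
    parameter-free instance-normalised features."""

    def __init__(self, channels: int, label_channels: int, hidden: int, rng):
        super().__init__()
        self.norm = nn.InstanceNorm(channels, affine=False)
        self.shared = nn.Conv(label_channels, hidden, 3, 1, 1, rng=rng)
        self.gamma = nn.Conv(hidden, channels, 3, 1, 1, rng=rng)
        self.beta = nn.Conv(hidden, channels, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor, seg: Tensor) -> Tensor:
        # pool the full-resolution semantic map down to x's grid
        factor = seg.shape[2] // x.shape[2]
        m = avg_pool(seg, factor) if factor > 1 else seg
        h = self.shared(m).leaky_relu(0.2)
        return self.norm.normalise_only(x) * (1.0 + self.gamma(h)) + self.beta(h)


class StyleFiLM(nn.Module):
    """Channel-wise scale/shift predicted from the style code.  Applied
    after each spatially-adaptive block so the contrast information in s
    survives the parameter-free normalisations."""

    def __init__(self, channels: int, style_dim: int, rng):
        super().__init__()
        self.fc = nn.Linear(style_dim, 2 * channels, rng=rng)
        # identity at initialisation: modulation grows only as the style
        # pathway proves useful, keeping early training stable
        self.fc.weight.data *= 0.0
        self.channels = channels

    def forward(self, x: Tensor, s: Tensor) -> Tensor:
        ab = self.fc(s)
        N = x.shape[0]
        a = ab[:, : self.channels].reshape(N, self.channels, 1, 1)
        b = ab[:, self.channels :].reshape(N, self.channels, 1, 1)
        return x * (1.0 + a) + b


class SpadeGenerator(nn.Module):
    """Style code + semantic map -> intensity image in [0, 1].

    Content enters through the spatially-adaptive blocks (scale/shift from
    the semantic map); style enters through the initial projection and a
    channel-wise modulation at every resolution.
    """

    def __init__(self, cfg: ImageGenConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed + 1)
        w, lc, sd = cfg.width, cfg.label_channels, cfg.style_dim
        self.base = cfg.image_size // 4
        self.w0 = w * 2
        self.fc = nn.Linear(sd, self.w0 * self.base * self.base, rng=rng)
        self.spade1 = SpadeBlock(self.w0, lc, w, rng)
        self.film1 = StyleFiLM(self.w0, sd, rng)
        self.conv1 = nn.Conv(self.w0, self.w0, 3, 1, 1, rng=rng)
        self.up1 = nn.Upsample(2)
        self.spade2 = SpadeBlock(self.w0, lc, w, rng)
        self.film2 = StyleFiLM(self.w0, sd, rng)
        self.conv2 = nn.Conv(self.w0, w, 3, 1, 1, rng=rng)
        self.up2 = nn.Upsample(2)
        self.spade3 = SpadeBlock(w, lc, w, rng)
        self.film3 = StyleFiLM(w, sd, rng)
        self.conv3 = nn.Conv(w, 1, 3, 1, 1, rng=rng)

    def forward(self, s: Tensor, seg: Tensor) -> Tensor:
        N = s.shape[0]
        h = self.fc(s).reshape(N, self.w0, self.base, self.base)
        h = self.conv1(self.film1(self.spade1(h, seg), s).leaky_relu(0.2))
        h = self.up1(h)
        h = self.conv2(self.film2(self.spade2(h, seg), s).leaky_relu(0.2))
        h = self.up2(h)
        h = self.conv3(self.film3(self.spade3(h, seg), s).leaky_relu(0.2))
        return h.sigmoid()


class PatchDisc(nn.Module):
    def __init__(self, cin: int, width: int, rng):
        super().__init__()
        self.c1 = nn.Conv(cin, width, 3, 2, 1, rng=rng)
        self.c2 = nn.Conv(width, width * 2, 3, 2, 1, rng=rng)
        self.c3 = nn.Conv(width * 2, 1, 3, 1, 1, rng=rng)

    def forward(self, x: Tensor):
        f1 = self.c1(x).leaky_relu(0.2)
        f2 = self.c2(f1).leaky_relu(0.2)
        return self.c3(f2), [f1, f2]


class MultiScaleDiscriminator(nn.Module):
    """N_D patch discriminators, each seeing a 2x further downsampled
    version of the (image || label || modality) stack."""

    def __init__(self, cfg: ImageGenConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed + 2)
        cin = 1 + cfg.label_channels + len(cfg.modalities)
        self.discs = [PatchDisc(cin, cfg.width, rng) for _ in range(cfg.n_disc_scales)]

    def forward(self, x: Tensor):
        scores, feats = [], []
        cur = x
        for i, d in enumerate(self.discs):
            if i > 0:
                cur = avg_pool(cur, 2)
            s, f = d(cur)
            scores.append(s)
            feats.append(f)
        return scores, feats


def discriminator_input(
    image: np.ndarray | Tensor, label: np.ndarray | Tensor, modality_onehot: np.ndarray
) -> Tensor:
    """Channel concatenation [image || label channels || broadcast one-hot
    modality planes]; fixed order."""
    img = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
    lab = label if isinstance(label, Tensor) else Tensor(np.asarray(label, dtype=np.float32))
    N = img.shape[0]
    H, W = img.shape[2], img.shape[3]
    m = np.asarray(modality_onehot, dtype=np.float32).reshape(N, -1, 1, 1)
    planes = Tensor(np.broadcast_to(m, (N, m.shape[1], H, W)).copy())
    return nn.concat([img, lab, planes], axis=1)


# ---------------------------------------------------------------------------
# triplets
# ---------------------------------------------------------------------------

@dataclass
class TrainingTriplet:
    """Semantic map m with its paired image i, plus a style image i_s from
    a different slice of the same volume and contrast."""

    m: np.ndarray  # (C, H, W) label slice
    i: np.ndarray  # (H, W) ground-truth image slice
    i_s: np.ndarray  # (H, W) style slice, same volume/modality
    modality: str
    dataset_tag: str = ""
    subject_id: str = ""
    slice_index: int = 0
    style_slice_index: int = 0


def make_training_triplet(
    label_volume: ProbLabelMap,
    image_volume: np.ndarray,
    modality: str,
    rng_seed: int,
    min_brain_fraction: float = 0.01,
) -> TrainingTriplet:
    """Draw a (map, image, style image) triplet from one volume: the style
    slice differs from the content slice whenever more than one usable
    slice exists (single-slice volumes reuse the slice, with a warning)."""
    if not label_volume.is_3d:
        raise LabelMapError("make_training_triplet requires a 3D label volume")
    rng = np.random.default_rng(rng_seed)
    usable = [
        k
        for k in range(label_volume.spatial_shape[-1])
        if label_volume.axial_slice(k).brain_mask().mean() >= min_brain_fraction
    ]
    if not usable:
        raise LabelMapError("volume has no usable slices")
    k = int(rng.choice(usable))
    if len(usable) == 1:
        logger.warning("single usable slice in %s: style slice equals content slice",
                       label_volume.subject_id)
        ks = k
    else:
        others = [j for j in usable if j != k]
        ks = int(rng.choice(others))
    sl = label_volume.axial_slice(k)
    return TrainingTriplet(
        m=sl.array,
        i=image_volume[..., k].astype(np.float32),
        i_s=image_volume[..., ks].astype(np.float32),
        modality=modality,
        dataset_tag=label_volume.dataset_tag,
        subject_id=label_volume.subject_id,
        slice_index=k,
        style_slice_index=ks,
    )


# ---------------------------------------------------------------------------
# the generator handle
# ---------------------------------------------------------------------------

class ImageGenerator(nn.Module):
    """Bundled style encoder + SPADE decoder."""

    def __init__(self, cfg: ImageGenConfig):
        super().__init__()
        self.cfg = cfg
        self.encoder = StyleEncoder(cfg)
        self.decoder = SpadeGenerator(cfg)

    def encode_style(self, image: np.ndarray, rng_seed: int = 0,
                     modality: str = "", dataset_tag: str = "") -> StyleCode:
        """Encode a normalised 2D image into a style code; eval mode
        returns the posterior mean as the sample."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim != 2 or img.shape != (self.cfg.image_size, self.cfg.image_size):
            raise ValueError(
                f"expected a ({self.cfg.image_size}, {self.cfg.image_size}) image, got {img.shape}"
            )
        with no_grad():
            m, lv = self.encoder.stats(Tensor(img[None, None]))
        mean, logvar = m.data[0], lv.data[0]
        if self.training:
            eps = np.random.default_rng(rng_seed).standard_normal(mean.shape)
            s = mean + np.exp(logvar / 2.0) * eps
        else:
            s = mean.copy()
        return StyleCode(mean=mean, logvar=logvar, s=s.astype(np.float32),
                         modality=modality, dataset_tag=dataset_tag)

    def generate_image(self, m: ProbLabelMap, s: StyleCode) -> np.ndarray:
        """Render the semantic map in the given style; 2D maps only (3D
        volumes are assembled slice by slice by the pipeline)."""
        if m.is_3d:
            raise LabelMapError("generate_image takes a 2D map; use the pipeline for volumes")
        with no_grad():
            out = self.decoder(
                Tensor(np.asarray(s.s, dtype=np.float32)[None]),
                Tensor(m.array[None].astype(np.float32)),
            )
        return out.data[0, 0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class PixelPlusRandomExtractor(nn.Module):
    """Perceptual backbone for images: the identity (raw pixels) plus a
    fixed-seed random convolutional stack, so the perceptual term contains
    a plain L1 component alongside texture-sensitive features."""

    def __init__(self, seed: int = 4321, width: int = 8):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.c1 = nn.Conv(1, width, 3, 2, 1, rng=rng)
        self.c2 = nn.Conv(width, width * 2, 3, 2, 1, rng=rng)

    def features(self, x: Tensor) -> list[Tensor]:
        f1 = self.c1(x).leaky_relu(0.2)
        f2 = self.c2(f1).leaky_relu(0.2)
        return [x, f1, f2]


@dataclass
class ImageGenTrainConfig:
    epochs: int = 20
    warmup_epochs: int = 5  # both nets train unconditionally before the
    # adversarial scheduler starts gating updates
    batch_size: int = 16
    lr: float = 2e-3
    disc_lr: float = 8e-3
    seed: int = 0
    lambda_gan: float = 0.1
    lambda_kld: float = 0.02
    lambda_perc: float = 8.0
    lambda_feat: float = 0.5
    lambda_cont: float = 1.0
    lambda_mod: float = 0.0  # modality/dataset discrimination loss: off by
    lambda_dat: float = 0.0  # default (removed after the ablation outcome)
    unpaired_styles: bool = True
    model: ImageGenConfig = field(default_factory=ImageGenConfig)


def discriminator_accuracy(scores_real, scores_fake) -> float:
    """Fraction of patches on the correct hinge side of 0, averaged over
    patches and individual discriminators."""
    accs = []
    for r, f in zip(scores_real, scores_fake):
        accs.append(float(np.mean(np.concatenate([(r.data > 0).ravel(), (f.data < 0).ravel()]))))
    return float(np.mean(accs))


def train_image_generator(
    triplets: list[TrainingTriplet], config: ImageGenTrainConfig, aux_classifier=None
):
    """Alternating VAE-GAN training over training triplets.

    Returns ``(model, history)``; history rows carry the per-epoch mean
    generator/discriminator losses and the scheduler's gating fractions.
    """
    if not triplets:
        raise ValueError("no training triplets")
    cfg = config.model
    rng = np.random.default_rng(config.seed)
    model = ImageGenerator(cfg)
    disc = MultiScaleDiscriminator(cfg)
    extractor = PixelPlusRandomExtractor(seed=4321)
    opt_g = nn.Adam(model.parameters(), lr=config.lr)
    opt_d = nn.Adam(disc.parameters(), lr=config.disc_lr)
    sched = SchedulerState()
    mod_index = {m: i for i, m in enumerate(cfg.modalities)}

    maps = np.stack([t.m for t in triplets]).astype(np.float32)
    imgs = np.stack([t.i for t in triplets]).astype(np.float32)[:, None]
    styles = np.stack([t.i_s for t in triplets]).astype(np.float32)[:, None]
    onehots = np.zeros((len(triplets), len(cfg.modalities)), dtype=np.float32)
    for j, t in enumerate(triplets):
        onehots[j, mod_index[t.modality]] = 1.0

    n = len(triplets)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        g_sum = d_sum = 0.0
        g_steps = d_steps = nb = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            seg = Tensor(maps[idx])
            real = Tensor(imgs[idx])
            style_src = styles[idx] if config.unpaired_styles else imgs[idx]
            onehot = onehots[idx]

            # generator pass
            s_mean, s_logvar = model.encoder.stats(Tensor(style_src))
            eps = Tensor(rng.standard_normal(s_mean.shape).astype(np.float32))
            s = s_mean + (s_logvar * 0.5).exp() * eps
            fake = model.decoder(s, seg)

            use_gan = config.lambda_gan > 0 or config.lambda_feat > 0
            if use_gan:
                d_fake_scores, d_fake_feats = disc(discriminator_input(fake, seg, onehot))
                d_real_scores, d_real_feats = disc(discriminator_input(real, seg, onehot))
                acc = discriminator_accuracy(d_real_scores, d_fake_scores)
                train_g, train_d, sched = scheduler_step(sched, acc)
                if epoch < config.warmup_epochs:
                    train_g = train_d = True
            else:
                train_g, train_d = True, False

            if train_g:
                from .autoencoder import gaussian_kld

                if config.lambda_gan > 0:
                    g_loss = hinge_gan_loss(None, d_fake_scores, side="generator") * config.lambda_gan
                else:
                    g_loss = Tensor(np.float64(0.0))
                g_loss = g_loss + gaussian_kld(s_mean, s_logvar) * config.lambda_kld
                g_loss = g_loss + perceptual_loss(real, fake, extractor) * config.lambda_perc
                if config.lambda_feat > 0:
                    g_loss = g_loss + feature_matching_loss(d_real_feats, d_fake_feats) * config.lambda_feat
                if config.lambda_cont > 0:
                    g_loss = g_loss + contrastive_style_loss(
                        model.encoder, style_src[:, 0], random_affine,
                        int(rng.integers(0, 2**31 - 1)),
                    ) * config.lambda_cont
                if config.lambda_mod > 0 or config.lambda_dat > 0:
                    g_loss = g_loss + modality_dataset_disc_loss(
                        aux_classifier, fake.data[:, 0], onehot, onehot,
                        config.lambda_mod, config.lambda_dat,
                    )
                if not np.isfinite(g_loss.item()):
                    raise RuntimeError("image generator training diverged (NaN loss)")
                opt_g.zero_grad()
                opt_d.zero_grad()
                g_loss.backward()
                opt_g.step()
                g_sum += g_loss.item()
                g_steps += 1

            if train_d:
                fake_det = Tensor(fake.data.copy())
                sr, _ = disc(discriminator_input(real, seg, onehot))
                sf, _ = disc(discriminator_input(fake_det, seg, onehot))
                d_loss = hinge_gan_loss(sr, sf, side="discriminator")
                if not np.isfinite(d_loss.item()):
                    raise RuntimeError("discriminator training diverged (NaN loss)")
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()
                d_sum += d_loss.item()
                d_steps += 1
            nb += 1
        history.append(
            {
                "g_loss": g_sum / max(g_steps, 1),
                "d_loss": d_sum / max(d_steps, 1),
                "g_frac": g_steps / nb,
                "d_frac": d_steps / nb,
            }
        )
    model.eval()
    disc.eval()
    return model, history
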