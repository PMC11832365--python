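"""Latent diffusion model over the label VAE's latent space.

The second stage of the label generator: a time-conditioned denoising
U-Net trained with epsilon-prediction on a fixed-variance forward process
(T = 1000 steps by default), with cross-attention conditioning on the
per-lesion disease proportions (and, for 2D slices, the relative axial
slice position).  Sampling uses a deterministic DDIM trajectory over an
evenly spaced timestep subset (200 steps by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .types import COUNT_THRESHOLD, LESION_CHANNELS, LabelMapError, ProbLabelMap

CONDITIONING_ORDER = LESION_CHANNELS  # (WMH, NE_tumour, oedema, GD_tumour)


# ---------------------------------------------------------------------------
# noise schedule
# ---------------------------------------------------------------------------

@dataclass
class NoiseSchedule:
    """Fixed-variance forward-process tables: beta_t, alpha_t = 1 - beta_t,
    and the cumulative product alpha_bar_t, indexed t = 1..T (0-based arrays)."""

    T: int
    betas: np.ndarray
    alphas: np.ndarray
    alpha_bars: np.ndarray

    def validate(self) -> None:
        if not ((self.betas > 0).all() and (self.betas < 1).all()):
            raise ValueError("betas must lie in (0, 1)")
        if not (np.diff(self.alpha_bars) < 0).all():
            raise ValueError("alpha_bar must be strictly decreasing")
        recur = np.empty_like(self.alpha_bars)
        recur[0] = self.alphas[0]
        recur[1:] = self.alpha_bars[:-1] * self.alphas[1:]
        if np.abs(recur - self.alpha_bars).max() > 1e-12:
            raise ValueError("alpha_bar recursion violated")


def make_schedule(T: int, kind: str = "linear") -> NoiseSchedule:
    """Linear beta schedule 1e-4 -> 0.02 over 1000 steps; for other T the
    endpoints are scaled by 1000/T so the terminal alpha_bar is preserved."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind != "linear":
        raise ValueError(f"unknown schedule kind {kind!r}")
    ref = np.linspace(1e-4, 0.02, 1000, dtype=np.float64)
    if T == 1000:
        betas = ref
    else:
        # subsample the reference chain in cumulative log-survival space so
        # the terminal alpha_bar is preserved exactly
        log_ab = np.concatenate([[0.0], np.cumsum(np.log1p(-ref))])
        pos = np.linspace(0, 1000, T + 1)
        cum = np.interp(pos, np.arange(1001), log_ab)
        betas = -np.expm1(np.diff(cum))
    betas = np.clip(betas, 1e-8, 0.999)
    alphas = 1.0 - betas
    sched = NoiseSchedule(T=T, betas=betas, alphas=alphas, alpha_bars=np.cumprod(alphas))
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

@dataclass
class ConditioningVector:
    """Lesion proportions P_c in [0,1] (fixed order: WMH, NE tumour, oedema,
    GD tumour) plus an optional relative slice position for 2D models."""

    proportions: dict[str, float] = field(default_factory=dict)
    slice_position: float | None = None

    def to_array(self, with_slice: bool) -> np.ndarray:
        vals = []
        for name in CONDITIONING_ORDER:
            v = float(self.proportions.get(name, 0.0))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"conditioning {name}={v} outside [0, 1]")
            vals.append(v)
        if with_slice:
            sp = 0.0 if self.slice_position is None else float(self.slice_position)
            if not 0.0 <= sp < 1.0:
                raise ValueError("slice position must lie in [0, 1)")
            vals.append(sp)
        return np.asarray(vals, dtype=np.float32)


def lesion_proportion(labels: list[ProbLabelMap], lesion_type: str) -> np.ndarray:
    """Per-sample lesion proportion: voxel count of the lesion channel
    (thresholded at 0.5) divided by the maximum count across the dataset.
    If no sample carries the lesion, all proportions are 0."""
    if not labels:
        raise LabelMapError("empty dataset")
    if lesion_type not in LESION_CHANNELS:
        raise LabelMapError(f"unknown lesion type {lesion_type!r}")
    counts = np.array([lab.lesion_voxel_count(lesion_type) for lab in labels], dtype=np.float64)
    m = counts.max()
    return counts / m if m > 0 else np.zeros_like(counts)


def relative_slice_number(axial_index: int, max_dim: int = 256) -> float:
    """Relative slice position: axial index divided by the maximum axial
    dimension (256 for 1 mm template-registered volumes)."""
    if not 0 <= axial_index < max_dim:
        raise ValueError(f"axial index {axial_index} outside [0, {max_dim})")
    return axial_index / max_dim


# ---------------------------------------------------------------------------
# forward process and loss
# ---------------------------------------------------------------------------

def forward_diffuse(x0: np.ndarray, t, eps: np.ndarray, schedule: NoiseSchedule) -> np.ndarray:
    """Closed-form marginal: x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps.

    ``t`` is a timestep in [1, T], scalar or per-sample array (batched x0).
    """
    t_arr = np.asarray(t)
    if t_arr.min() < 1 or t_arr.max() > schedule.T:
        raise ValueError(f"t={t} outside [1, {schedule.T}]")
    if x0.shape != eps.shape:
        raise ValueError("x0 / eps shape mismatch")
    ab = schedule.alpha_bars[t_arr - 1]
    if t_arr.ndim > 0:
        ab = ab.reshape((-1,) + (1,) * (x0.ndim - 1))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def dm_loss(denoiser, x0, cond: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule):
    """Epsilon-prediction objective: L2 between the injected noise and the
    denoiser's estimate on the diffused latent."""
    x0d = x0.data if isinstance(x0, Tensor) else x0
    xt = forward_diffuse(x0d, t, eps, schedule)
    eps_hat = denoiser(Tensor(xt.astype(np.float32)), t, cond)
    diff = eps_hat - Tensor(eps.astype(np.float32))
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# denoiser
# ---------------------------------------------------------------------------

def _time_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal timestep embedding (t normalised by 1000)."""
    half = dim // 2
    freqs = np.exp(-np.log(1000.0) * np.arange(half) / max(half - 1, 1))
    ang = np.asarray(t, dtype=np.float64).reshape(-1, 1) * freqs.reshape(1, -1)
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)


@dataclass
class DenoiserConfig:
    latent_channels: int = 3
    width: int = 32
    cond_dim: int = 4  # 5 when slice position is appended (2D)
    token_dim: int = 8
    time_dim: int = 16
    ndim: int = 2
    seed: int = 0


class CondUNet(nn.Module):
    """Small time-conditioned U-Net over the latent grid with single-head
    cross-attention on the conditioning token sequence at the bottleneck.

    Each conditioning scalar becomes one token: value * embedding + bias,
    so the attention keys/values carry both which lesion a token denotes
    and how much of it is requested.
    """

    def __init__(self, config: DenoiserConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        zc, w, nd = config.latent_channels, config.width, config.ndim
        self.inc = nn.Conv(zc, w, 3, 1, 1, ndim=nd, rng=rng)
        self.time1 = nn.Linear(config.time_dim, w, rng=rng)
        self.down = nn.Conv(w, 2 * w, 3, 2, 1, ndim=nd, rng=rng)
        self.time2 = nn.Linear(config.time_dim, 2 * w, rng=rng)
        self.mid1 = nn.Conv(2 * w, 2 * w, 3, 1, 1, ndim=nd, rng=rng)
        self.token_w = nn.Parameter(
            rng.standard_normal((config.cond_dim, config.token_dim)) * 0.5
        )
        self.token_b = nn.Parameter(rng.standard_normal((config.cond_dim, config.token_dim)) * 0.1)
        self.attn = nn.CrossAttention(2 * w, config.token_dim, rng=rng)
        self.mid2 = nn.Conv(2 * w, 2 * w, 3, 1, 1, ndim=nd, rng=rng)
        self.up = nn.Upsample(2)
        self.upc = nn.Conv(2 * w, w, 3, 1, 1, ndim=nd, rng=rng)
        self.outc = nn.Conv(2 * w, zc, 3, 1, 1, ndim=nd, rng=rng)

    def tokens(self, cond: np.ndarray) -> Tensor:
        """(N, cond_dim) conditioning values -> (N, cond_dim, token_dim)."""
        c = Tensor(np.asarray(cond, dtype=np.float32).reshape(-1, self.config.cond_dim, 1))
        return c * self.token_w + self.token_b

    def forward(self, xt: Tensor, t, cond) -> Tensor:
        """Predict the injected noise for noisy latents ``xt`` at timestep
        ``t`` (scalar or per-sample array) under conditioning ``cond``
        (array (N, cond_dim))."""
        N = xt.shape[0]
        nd = self.config.ndim
        if any(s % 2 for s in xt.shape[2:]):
            raise ValueError(
                f"denoiser latent spatial dims must be even, got {xt.shape[2:]}"
            )
        t_arr = np.broadcast_to(np.asarray(t, dtype=np.float64) / 1000.0, (N,))
        temb = Tensor(_time_embedding(t_arr, self.config.time_dim))
        cond = np.broadcast_to(
            np.asarray(cond, dtype=np.float32).reshape(-1, self.config.cond_dim),
            (N, self.config.cond_dim),
        )
        bshape = (N, -1) + (1,) * nd

        h1 = self.inc(xt)
        h1 = (h1 + self.time1(temb).reshape(*bshape)).leaky_relu(0.2)
        h2 = self.down(h1)
        h2 = (h2 + self.time2(temb).reshape(*bshape)).leaky_relu(0.2)
        h2 = self.mid1(h2).leaky_relu(0.2)
        h2 = self.attn(h2, self.tokens(cond))
        h2 = self.mid2(h2).leaky_relu(0.2)
        u = self.upc(self.up(h2)).leaky_relu(0.2)
        return self.outc(nn.concat([u, h1], axis=1))

    def predict(self, xt: np.ndarray, t, cond: np.ndarray) -> np.ndarray:
        from .nn.tensor import no_grad

        with no_grad():
            return self.forward(Tensor(xt.astype(np.float32)), t, cond).data


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def ddim_timesteps(T: int, n_steps: int) -> np.ndarray:
    """Evenly spaced increasing timestep subset in [1, T] ending at T."""
    if not 1 <= n_steps <= T:
        raise ValueError(f"n_steps={n_steps} outside [1, {T}]")
    return np.unique(np.linspace(1, T, n_steps).round().astype(int))


def ddim_sample(
    denoiser,
    cond: np.ndarray,
    schedule: NoiseSchedule,
    latent_shape: tuple[int, ...],
    n_steps: int = 200,
    rng_seed: int = 0,
    n_samples: int = 1,
) -> np.ndarray:
    """Deterministic DDIM sampling (eta = 0) over an evenly spaced timestep
    subset.  Returns latents of shape (n_samples, *latent_shape)."""
    steps = ddim_timesteps(schedule.T, n_steps)
    rng = np.random.default_rng(rng_seed)
    x = rng.standard_normal((n_samples,) + tuple(latent_shape)).astype(np.float32)
    cond = np.broadcast_to(
        np.asarray(cond, dtype=np.float32).reshape(1, -1), (n_samples, np.shape(cond)[-1])
    ) if np.ndim(cond) == 1 else np.asarray(cond, dtype=np.float32)
    for i in range(len(steps) - 1, -1, -1):
        t = int(steps[i])
        ab_t = schedule.alpha_bars[t - 1]
        ab_prev = schedule.alpha_bars[steps[i - 1] - 1] if i > 0 else 1.0
        eps_hat = denoiser.predict(x, t, cond) if hasattr(denoiser, "predict") else denoiser(x, t, cond)
        x0_pred = (x - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
        x = np.sqrt(ab_prev) * x0_pred + np.sqrt(1.0 - ab_prev) * eps_hat
    return x.astype(np.float32)


def finalise_label(decoded: ProbLabelMap) -> ProbLabelMap:
    """Restore full label-map invariants on a decoded map: binarise lesion
    channels at the counting threshold, zero healthy tissue under lesions,
    renormalise healthy channel sums to <= 1."""
    arr = decoded.array.copy()
    les = decoded.lesion_indices
    heal = decoded.healthy_indices
    arr[les] = (arr[les] > COUNT_THRESHOLD).astype(np.float32)
    lesion_on = arr[les].max(axis=0) >= 0.5 if les else np.zeros(arr.shape[1:], bool)
    for i in heal:
        arr[i][lesion_on] = 0.0
    total = arr[heal].sum(axis=0, keepdims=True)
    scale = np.where(total > 1.0, total, 1.0)
    arr[heal] = arr[heal] / scale
    out = ProbLabelMap(array=arr, channel_names=decoded.channel_names)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# training and the trained-generator handle
# ---------------------------------------------------------------------------

@dataclass
class DiffusionTrainConfig:
    epochs: int = 150
    batch_size: int = 64
    lr: float = 2e-3
    T: int = 1000
    seed: int = 0
    width: int = 48
    use_slice_position: bool | None = None  # None: auto (2D with axial index)


@dataclass
class LabelGenerator:
    """Trained label generator: frozen VAE + conditioned denoiser +
    schedule + the latent scaling and conditioning statistics needed at
    sampling time."""

    vae: object
    denoiser: CondUNet
    schedule: NoiseSchedule
    latent_std: float
    latent_shape: tuple[int, ...]
    with_slice: bool
    cond_quartiles: dict[str, tuple[float, float]]

    def sample_labels(
        self,
        conds: list[ConditioningVector],
        n_steps: int = 200,
        rng_seed: int = 0,
    ) -> list[ProbLabelMap]:
        """DDIM-sample one label map per conditioning vector."""
        if not conds:
            return []
        cond_arr = np.stack([c.to_array(self.with_slice) for c in conds])
        lat = ddim_sample(
            self.denoiser,
            cond_arr,
            self.schedule,
            self.latent_shape,
            n_steps=n_steps,
            rng_seed=rng_seed,
            n_samples=len(conds),
        )
        out = []
        for i in range(len(conds)):
            dec = self.vae.decode(lat[i] * self.latent_std)
            out.append(finalise_label(dec))
        return out


def dataset_conditionings(
    labels: list[ProbLabelMap], with_slice: bool
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Per-sample conditioning arrays plus the (Q1, Q3) quartiles of the
    nonzero proportions per lesion type (used for random conditioning draws)."""
    cols = []
    quartiles: dict[str, tuple[float, float]] = {}
    for name in CONDITIONING_ORDER:
        p = lesion_proportion(labels, name)
        cols.append(p)
        nz = p[p > 0]
        quartiles[name] = (
            (float(np.percentile(nz, 25)), float(np.percentile(nz, 75))) if nz.size else (0.0, 0.0)
        )
    if with_slice:
        cols.append(
            np.array(
                [
                    relative_slice_number(lab.axial_index, 256)
                    if lab.axial_index is not None
                    else 0.0
                    for lab in labels
                ]
            )
        )
    return np.stack(cols, axis=1).astype(np.float32), quartiles


def train_label_diffusion(
    vae, dataset: list[ProbLabelMap], config: DiffusionTrainConfig
) -> tuple[LabelGenerator, list[float]]:
    """Train the conditioned latent diffusion model on a frozen VAE's
    latents.  The VAE must be in eval mode (two-stage contract).  Latents
    are standardised by their global standard deviation before diffusion.
    """
    if vae.training:
        raise LabelMapError("VAE must be frozen (eval mode) before diffusion training")
    if not dataset:
        raise LabelMapError("empty dataset")
    rng = np.random.default_rng(config.seed)
    lats = np.stack([vae.encode(lab).mean for lab in dataset]).astype(np.float32)
    latent_std = float(lats.std()) or 1.0
    lats /= latent_std
    with_slice = (
        config.use_slice_position
        if config.use_slice_position is not None
        else any(lab.axial_index is not None for lab in dataset) and not dataset[0].is_3d
    )
    conds, quartiles = dataset_conditionings(dataset, with_slice)
    schedule = make_schedule(config.T)
    den_cfg = DenoiserConfig(
        latent_channels=lats.shape[1],
        width=config.width,
        cond_dim=conds.shape[1],
        ndim=lats.ndim - 2,
        seed=config.seed,
    )
    den = CondUNet(den_cfg)
    opt = nn.Adam(den.parameters(), lr=config.lr)
    n = len(lats)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x0 = lats[idx]
            t = rng.integers(1, schedule.T + 1, size=len(idx))
            eps = rng.standard_normal(x0.shape).astype(np.float32)
            loss = dm_loss(den, x0, conds[idx], t, eps, schedule)
            if not np.isfinite(loss.item()):
                raise RuntimeError("diffusion training diverged (NaN loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            nb += 1
        history.append(ep_loss / nb)
    den.eval()
    gen = LabelGenerator(
        vae=vae,
        denoiser=den,
        schedule=schedule,
        latent_std=latent_std,
        latent_shape=tuple(lats.shape[1:]),
        with_slice=with_slice,
        cond_quartiles=quartiles,
    )
    return gen, history
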