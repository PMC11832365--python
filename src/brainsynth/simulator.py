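"""Statistics-derived (SD) image simulator.

Given a probabilistic label map L with regions i, a modality m and a dataset
d, the simulated image is

    SD(m, L) = BF * sum_i  L_i * N(mu_{m,d,i}, sigma_{m,d,i} / K)

where (mu, sigma) are per-region intensity statistics, K a modality-dependent
contrast factor that sharpens tissue separation, and BF a random smooth
multiplicative bias field applied with a configured probability.  The
Gaussian is drawn per voxel by default (``per_region=True`` draws one value
per region, spatially constant).

The simulator doubles as the source of phantom training images and as the
comparison baseline for the learned image generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ALL_CHANNELS, ProbLabelMap


class StatsError(KeyError):
    """Raised when intensity statistics are missing or degenerate."""


@dataclass
class RegionIntensityStats:
    """Per (modality, dataset, region) intensity mean/std plus per-modality
    contrast factor K (> 0, dimensionless)."""

    entries: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    contrast_K: dict[str, float] = field(default_factory=dict)

    def set(self, modality: str, dataset: str, region: str, mu: float, sigma: float) -> None:
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.entries[(modality, dataset, region)] = (float(mu), float(sigma))

    def get(self, modality: str, dataset: str, region: str) -> tuple[float, float]:
        try:
            return self.entries[(modality, dataset, region)]
        except KeyError:
            raise StatsError(f"no stats for ({modality}, {dataset}, {region})") from None

    def K(self, modality: str) -> float:
        k = self.contrast_K.get(modality, 1.0)
        if k <= 0:
            raise ValueError("contrast factor K must be > 0")
        return k

    def covers(self, modality: str, dataset: str, regions) -> bool:
        return all((modality, dataset, r) in self.entries for r in regions)

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": [
                    {"modality": m, "dataset": d, "region": r, "mu": mu, "sigma": sg}
                    for (m, d, r), (mu, sg) in self.entries.items()
                ],
                "contrast_K": self.contrast_K,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RegionIntensityStats":
        obj = json.loads(text)
        st = cls(contrast_K=dict(obj.get("contrast_K", {})))
        for e in obj["entries"]:
            st.set(e["modality"], e["dataset"], e["region"], e["mu"], e["sigma"])
        return st


@dataclass
class BiasFieldParams:
    """Multiplicative bias-field settings: log-amplitude coefficient drawn
    uniformly in ``coeff_range``, applied with ``probability``; the field is
    the exponential of a smooth low-order random surface."""

    coeff_range: tuple[float, float] = (0.05, 0.15)
    probability: float = 0.4
    control_points: int = 4

    def validate(self) -> None:
        lo, hi = self.coeff_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("coefficient range must lie within [0, 1)")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")


_DEFAULT_SIGMA = 5.0

#: plausible MR intensity means (arbitrary units, 0-100 scale) giving the
#: canonical contrast orderings: T1 (WM bright, CSF dark), FLAIR (WMH/oedema
#: bright, CSF suppressed), T2 (CSF bright, WM dark).
_DEFAULT_MEANS = {
    "T1": {
        "CSF": 10, "GM": 60, "WM": 80, "DGM": 55, "brainstem": 70,
        "WMH": 45, "NE_tumour": 35, "oedema": 50, "GD_tumour": 90,
    },
    "FLAIR": {
        "CSF": 5, "GM": 60, "WM": 48, "DGM": 55, "brainstem": 52,
        "WMH": 95, "NE_tumour": 45, "oedema": 85, "GD_tumour": 60,
    },
    "T2": {
        "CSF": 95, "GM": 65, "WM": 45, "DGM": 55, "brainstem": 50,
        "WMH": 85, "NE_tumour": 70, "oedema": 90, "GD_tumour": 60,
    },
}


def default_phantom_stats(
    dataset_tag: str = "phantom", modalities=("T1", "FLAIR", "T2"), K: float = 1.5
) -> RegionIntensityStats:
    """Region statistics emulating T1 / FLAIR / T2 contrast for phantoms.

    With sigma = 5 and K = 1.5 the GM/WM contrast-to-noise ratio is
    |mu_GM - mu_WM| / (sigma / K) >= 3 in every modality.
    """
    st = RegionIntensityStats()
    for m in modalities:
        st.contrast_K[m] = K
        for r in ALL_CHANNELS:
            st.set(m, dataset_tag, r, _DEFAULT_MEANS[m][r], _DEFAULT_SIGMA)
    return st


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_region_stats(
    images: list[np.ndarray],
    labels: list[ProbLabelMap],
    modality: str,
    dataset_tag: str,
    into: RegionIntensityStats | None = None,
    regions: list[str] | None = None,
) -> RegionIntensityStats:
    """Probability-weighted per-region intensity mean/std over a paired set.

    For region channel i with weights w = L_i across all provided voxels,
    mu = sum(w x)/sum(w) and sigma^2 = sum(w (x-mu)^2)/sum(w).  By default
    only regions present in the set are estimated; requesting an explicit
    ``regions`` list makes a zero-mass region an error naming the region.
    """
    if len(images) != len(labels) or not images:
        raise ValueError("images and labels must be equal-length non-empty lists")
    st = into if into is not None else RegionIntensityStats()
    names = labels[0].channel_names
    wanted = set(regions) if regions is not None else None
    for ci, region in enumerate(names):
        if wanted is not None and region not in wanted:
            continue
        wsum = 0.0
        wx = 0.0
        for img, lab in zip(images, labels):
            w = lab.array[ci].astype(np.float64)
            wsum += w.sum()
            wx += (w * img).sum()
        if wsum <= 0:
            if wanted is not None:
                raise StatsError(f"region {region!r} has zero probability mass")
            continue
        mu = wx / wsum
        wv = 0.0
        for img, lab in zip(images, labels):
            w = lab.array[ci].astype(np.float64)
            wv += (w * (img - mu) ** 2).sum()
        st.set(modality, dataset_tag, region, mu, float(np.sqrt(wv / wsum)))
    return st


def sample_bias_field(
    shape: tuple[int, ...], params: BiasFieldParams, rng_seed: int
) -> np.ndarray:
    """Smooth, strictly positive multiplicative field with mean ~ 1.

    A coarse grid of standard-normal control points is spline-interpolated
    to full resolution, scaled to unit maximum deviation, multiplied by a
    coefficient drawn uniformly in ``coeff_range`` and exponentiated.
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    lo, hi = params.coeff_range
    coeff = rng.uniform(lo, hi)
    n = params.control_points
    coarse = rng.standard_normal((n,) * len(shape))
    zooms = [s / n for s in shape]
    smooth = ndimage.zoom(coarse, zooms, order=3, mode="nearest")
    # exact output shape (zoom can be off by one on odd ratios)
    smooth = smooth[tuple(slice(0, s) for s in shape)]
    pad = [(0, s - cs) for s, cs in zip(shape, smooth.shape)]
    if any(p[1] for p in pad):
        smooth = np.pad(smooth, pad, mode="edge")
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth = smooth / peak
    return np.exp(coeff * smooth)


def sd_image(
    label: ProbLabelMap,
    stats: RegionIntensityStats,
    modality: str,
    dataset_tag: str,
    params: BiasFieldParams | None = None,
    rng_seed: int = 0,
    per_region: bool = False,
) -> np.ndarray:
    """Simulate one statistics-derived intensity image from a label map.

    Per-voxel intensity is the label-weighted sum of Gaussian draws
    N(mu_i, sigma_i / K); a random bias field multiplies the result with
    the configured probability; output is clipped to be non-negative.
    """
    params = params or BiasFieldParams()
    params.validate()
    rng = np.random.default_rng(rng_seed)
    K = stats.K(modality)
    shape = label.spatial_shape
    img = np.zeros(shape, dtype=np.float64)
    for ci, region in enumerate(label.channel_names):
        L = label.array[ci]
        if L.max() <= 0:
            continue  # region absent from this map; stats not required
        mu, sigma = stats.get(modality, dataset_tag, region)
        sd = sigma / K
        if per_region:
            draw = rng.normal(mu, sd) * np.ones(shape)
        else:
            draw = rng.normal(mu, sd, size=shape)
        img += L * draw
    if rng.random() < params.probability:
        img *= sample_bias_field(shape, params, int(rng.integers(0, 2**31 - 1)))
    return np.clip(img, 0.0, None).astype(np.float32)


def normalise_image(img: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Percentile rescale to [0, 1] — the image generator's input convention."""
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(img, dtype=np.float32)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)
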