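"""Quality, conditioning, fidelity and privacy diagnostics.

Covers the pipeline's evaluation surface: tissue-proportion profiles of
label sets (label-quality surrogate), lesion-size-versus-conditioning
curves, the tumour false-positive rate of WMH predictions, SSIM/MSE image
fidelity, Fréchet distance between feature distributions (pluggable
feature extractor), Dice-based nearest-neighbour retrieval (memorisation
check) and k-means clustering of style codes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .types import COUNT_THRESHOLD, LabelMapError, ProbLabelMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# label quality
# ---------------------------------------------------------------------------

@dataclass
class ProportionProfile:
    """Per-region mean/std of brain-mass proportion, either per axial slice
    (keys are slice indices) or whole-volume (single key ``-1``)."""

    regions: tuple[str, ...]
    mean: dict[int, np.ndarray] = field(default_factory=dict)
    std: dict[int, np.ndarray] = field(default_factory=dict)
    count: dict[int, int] = field(default_factory=dict)


def _region_proportions(lab: ProbLabelMap) -> np.ndarray:
    mass = lab.array.reshape(lab.n_channels, -1).sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise LabelMapError(f"label {lab.subject_id!r} has no brain mass")
    return mass / total


def tissue_proportion_profile(
    labels: list[ProbLabelMap], mode: str = "per_volume"
) -> ProportionProfile:
    """Proportion of brain mass per semantic region.

    ``per_volume``: one summary over whole maps (2D maps count as single
    slices).  ``per_slice``: grouped by the axial index recorded on 2D
    slices (3D volumes are sliced on the fly)."""
    if not labels:
        raise LabelMapError("empty label list")
    regions = labels[0].channel_names
    samples: dict[int, list[np.ndarray]] = {}
    if mode == "per_volume":
        samples[-1] = [_region_proportions(lab) for lab in labels]
    elif mode == "per_slice":
        for lab in labels:
            if lab.is_3d:
                for k in range(lab.spatial_shape[-1]):
                    sl = lab.axial_slice(k)
                    if sl.brain_mask().any():
                        samples.setdefault(k, []).append(_region_proportions(sl))
            else:
                k = lab.axial_index if lab.axial_index is not None else -1
                samples.setdefault(k, []).append(_region_proportions(lab))
    else:
        raise ValueError("mode must be 'per_slice' or 'per_volume'")
    prof = ProportionProfile(regions=regions)
    for k, rows in samples.items():
        arr = np.stack(rows)
        prof.mean[k] = arr.mean(axis=0)
        prof.std[k] = arr.std(axis=0)
        prof.count[k] = len(rows)
    return prof


def profile_coverage(
    reference: ProportionProfile, candidate: ProportionProfile, n_std: float = 3.0
) -> float:
    """Fraction of (region, slice) bins in which the candidate profile's
    mean lies within ``reference mean +/- n_std * reference std``."""
    hits = total = 0
    for k in reference.mean:
        if k not in candidate.mean:
            continue
        lo = reference.mean[k] - n_std * reference.std[k]
        hi = reference.mean[k] + n_std * reference.std[k]
        ok = (candidate.mean[k] >= lo) & (candidate.mean[k] <= hi)
        hits += int(ok.sum())
        total += ok.size
    if total == 0:
        raise ValueError("profiles share no bins")
    return hits / total


@dataclass
class ConditioningCurve:
    """Lesion-size summaries as a function of the conditioning value."""

    values: np.ndarray
    medians: np.ndarray
    iqrs: np.ndarray
    counts: list[np.ndarray]


def lesion_size_curve(
    sampler,
    cond_values,
    n_per_value: int,
    lesion_type: str,
    rng_seed: int = 0,
    n_steps: int = 200,
) -> ConditioningCurve:
    """Sample ``n_per_value`` labels at each conditioning value and record
    the thresholded lesion voxel counts."""
    from .diffusion import ConditioningVector

    values = np.sort(np.asarray(cond_values, dtype=float))
    medians, iqrs, counts = [], [], []
    for j, v in enumerate(values):
        conds = [ConditioningVector({lesion_type: float(v)})] * n_per_value
        labs = sampler.sample_labels(conds, n_steps=n_steps, rng_seed=rng_seed + j)
        c = np.array([lab.lesion_voxel_count(lesion_type) for lab in labs], dtype=float)
        counts.append(c)
        medians.append(np.median(c))
        q1, q3 = np.percentile(c, [25, 75]) if len(c) > 1 else (c[0], c[0])
        iqrs.append(q3 - q1)
    return ConditioningCurve(
        values=values, medians=np.array(medians), iqrs=np.array(iqrs), counts=counts
    )


# ---------------------------------------------------------------------------
# segmentation / image metrics
# ---------------------------------------------------------------------------

def fp_tum(wmh_prediction: np.ndarray, tumour_truth: np.ndarray) -> float:
    """Fraction of tumour voxels mislabelled as WMH:
    |prediction AND tumour| / |tumour|."""
    pred = np.asarray(wmh_prediction).astype(bool)
    tum = np.asarray(tumour_truth).astype(bool)
    if pred.shape != tum.shape:
        raise ValueError("shape mismatch")
    n_tum = tum.sum()
    if n_tum == 0:
        raise ZeroDivisionError("empty tumour mask")
    return float((pred & tum).sum() / n_tum)


def image_fidelity(i: np.ndarray, i_tilde: np.ndarray, data_range: float | None = None):
    """(SSIM, MSE) between two images.  SSIM uses the standard 7x7 window
    and default stabilisation constants (K1=0.01, K2=0.03)."""
    i = np.asarray(i, dtype=np.float64)
    j = np.asarray(i_tilde, dtype=np.float64)
    if i.shape != j.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        lo = min(i.min(), j.min())
        hi = max(i.max(), j.max())
        data_range = (hi - lo) or 1.0
    ssim = float(structural_similarity(i, j, data_range=data_range))
    mse = float(np.mean((i - j) ** 2))
    return ssim, mse


def fid_score(features_a: np.ndarray, features_b: np.ndarray, eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets:
    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The covariance square root is computed by eigen-decomposition with a
    small jitter added when a product matrix is near-singular (logged)."""
    a = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    ca = np.cov(a, rowvar=False).reshape(a.shape[1], a.shape[1])
    cb = np.cov(b, rowvar=False).reshape(b.shape[1], b.shape[1])
    prod = ca @ cb
    vals, vecs = np.linalg.eig(prod)
    if np.any(np.real(vals) < -eps):
        logger.info("near-singular covariance product; adding %g jitter", eps)
        ca = ca + eps * np.eye(len(ca))
        cb = cb + eps * np.eye(len(cb))
        vals, vecs = np.linalg.eig(ca @ cb)
    sqrt_vals = np.sqrt(np.clip(np.real(vals), 0.0, None))
    tr_sqrt = float(np.real(np.sum(sqrt_vals)))
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(ca) + np.trace(cb) - 2.0 * tr_sqrt)
    return max(d2, 0.0)


# ---------------------------------------------------------------------------
# privacy
# ---------------------------------------------------------------------------

def label_dice(a: ProbLabelMap, b: ProbLabelMap, threshold: float = COUNT_THRESHOLD) -> float:
    """Mean Dice over channels present (above threshold) in either map."""
    if a.channel_names != b.channel_names:
        raise LabelMapError("channel mismatch")
    dices = []
    for c in range(a.n_channels):
        x = a.array[c] > threshold
        y = b.array[c] > threshold
        nx, ny = x.sum(), y.sum()
        if nx == 0 and ny == 0:
            continue
        dices.append(2.0 * (x & y).sum() / (nx + ny))
    return float(np.mean(dices)) if dices else 1.0


def nn_dice_retrieval(
    query: ProbLabelMap, training_labels: list[ProbLabelMap], k: int = 4
) -> list[tuple[int, float]]:
    """Nearest neighbours of a query label in Dice, descending.

    Returns ``[(training index, dice), ...]`` of length ``min(k, n)``; a
    ``k`` larger than the set size returns everything (logged)."""
    if not training_labels:
        raise LabelMapError("empty training set")
    if k > len(training_labels):
        logger.info("k=%d exceeds set size %d; returning all", k, len(training_labels))
        k = len(training_labels)
    scores = [(i, label_dice(query, lab)) for i, lab in enumerate(training_labels)]
    scores.sort(key=lambda t: (-t[1], t[0]))
    return scores[:k]


def style_code_clustering(
    codes: np.ndarray,
    true_groups: list,
    k: int,
    rng_seed: int = 0,
    embedder=None,
):
    """K-means clustering of style codes (optional 2-D embedding first),
    scored as adjusted Rand index against the true groups.

    Returns ``(assignments, ari)``.  K-means uses random initialisation
    with 300 iterations, seeded.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    X = np.asarray(codes, dtype=np.float64)
    if len(X) < k:
        raise ValueError("fewer codes than clusters")
    if embedder is not None:
        X = embedder(X)
    km = KMeans(n_clusters=k, init="random", n_init=10, max_iter=300, random_state=rng_seed)
    assign = km.fit_predict(X)
    return assign, float(adjusted_rand_score(true_groups, assign))
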