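"""Brain phantom generator.

Produces probabilistic tissue label maps with the topology of a GIF-style
brain parcellation — an outer CSF shell, a grey-matter ribbon, a white-matter
interior, central deep-grey-matter blobs, a ventricular CSF surrogate and an
inferior brainstem stalk — built from jittered nested ellipsoids whose
boundaries are Gaussian-smoothed so border voxels carry genuinely fractional
probabilities.  Lesions (white-matter hyperintensities; three-compartment
tumours) are placed as binary masks and fused by zeroing healthy tissue
underneath them.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import (
    ALL_CHANNELS,
    HEALTHY_CHANNELS,
    LESION_CHANNELS,
    LabelMapError,
    LesionMask,
    ProbLabelMap,
)

MIN_INPLANE = 16

#: fraction of the outer brain radius occupied by each nested shell
_CSF_SHELL = 1.0
_GM_SHELL = 0.86
_WM_SHELL = 0.68


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    ``shape`` is spatial: ``(H, W)`` for 2D slices, ``(H, W, D)`` for
    volumes (axial axis last).  ``jitter`` perturbs ellipsoid semi-axes and
    centres by a uniform fraction.  ``lesion_frequency`` maps lesion kind
    (``"wmh"``, ``"tumour"``) to per-subject probability.  ``softness_vox``
    is the Gaussian boundary-smoothing sigma in voxels.
    """

    shape: tuple[int, ...] = (32, 32)
    n_subjects: int = 10
    jitter: float = 0.08
    lesion_frequency: dict[str, float] = field(default_factory=dict)
    lesion_radius_range: tuple[float, float] = (1.5, 4.5)
    softness_vox: float = 1.5
    allow_min_lesion: bool = True
    seed: int = 0
    dataset_tag: str = "phantom"

    def validate(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2D or 3D")
        if min(self.shape[:2]) < MIN_INPLANE:
            raise ValueError(f"in-plane shape must be at least {MIN_INPLANE}")
        if not 0.0 <= self.jitter <= 0.5:
            raise ValueError("jitter fraction must lie in [0, 0.5]")
        for k, v in self.lesion_frequency.items():
            if k not in ("wmh", "tumour") or not 0 <= v <= 1:
                raise ValueError(f"bad lesion frequency entry {k}={v}")


def _coordinate_grids(shape: tuple[int, ...]) -> list[np.ndarray]:
    return list(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"))


def _ellipsoid_r(grids, centre, axes) -> np.ndarray:
    """Normalised radial coordinate: r<1 inside the ellipsoid."""
    return np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, axes)))


def generate_phantom_label(config: PhantomConfig, rng_seed: int) -> ProbLabelMap:
    """Generate one healthy probabilistic phantom label map.

    The anatomy is a categorical nested-ellipsoid parcellation that is
    one-hot encoded (with an explicit background class), channel-wise
    Gaussian smoothed with ``config.softness_vox`` and renormalised so that
    the per-voxel sum over tissue channels stays <= 1, leaving fractional
    probabilities on every region border.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    shape = tuple(config.shape)
    grids = _coordinate_grids(shape)
    ndim = len(shape)

    def jit(scale: float = 1.0) -> float:
        return 1.0 + scale * rng.uniform(-config.jitter, config.jitter)

    centre = [s / 2.0 * jit(0.35) for s in shape]
    axes = [0.42 * s * jit() for s in shape]
    r_brain = _ellipsoid_r(grids, centre, axes)

    # categorical map: 0 bg, 1 CSF, 2 GM, 3 WM, 4 DGM, 5 brainstem
    cat = np.zeros(shape, dtype=np.int8)
    cat[r_brain <= _CSF_SHELL] = 1
    cat[r_brain <= _GM_SHELL] = 2
    cat[r_brain <= _WM_SHELL] = 3

    # ventricular CSF surrogate: small central ellipse pair inside WM
    for side in (-1.0, 1.0):
        v_centre = list(centre)
        v_centre[1] += side * 0.10 * shape[1] * jit()
        v_axes = [0.055 * s * jit() for s in shape]
        v_axes[0] *= 1.6  # elongated along rows
        inside = _ellipsoid_r(grids, v_centre, v_axes) <= 1.0
        cat[inside & (cat == 3)] = 1

    # deep grey matter: two blobs flanking the ventricles
    for side in (-1.0, 1.0):
        d_centre = list(centre)
        d_centre[1] += side * 0.20 * shape[1] * jit()
        d_axes = [0.085 * s * jit() for s in shape]
        inside = _ellipsoid_r(grids, d_centre, d_axes) <= 1.0
        cat[inside & (cat == 3)] = 4

    # brainstem: inferior stalk.  In-plane "inferior" is high row index; in
    # 3D the stalk additionally sits in the lower axial slices.
    b_centre = list(centre)
    b_centre[0] = centre[0] + 0.30 * shape[0] * jit()
    b_axes = [0.10 * s * jit() for s in shape]
    b_axes[0] *= 1.8
    if ndim == 3:
        b_centre[2] = 0.22 * shape[2]
        b_axes[2] = 0.30 * shape[2] * jit()
    inside = _ellipsoid_r(grids, b_centre, b_axes) <= 1.0
    cat[inside & (cat > 0)] = 5

    # sanity: all five regions must be present
    present = set(np.unique(cat))
    missing = {1, 2, 3, 4, 5} - present
    if missing:
        raise LabelMapError(
            f"shape {shape} too small to fit all regions (missing ids {sorted(missing)})"
        )

    # one-hot incl. background, smooth, renormalise
    onehot = np.stack([(cat == k).astype(np.float64) for k in range(6)])
    if config.softness_vox > 0:
        sig = (0.0,) + (config.softness_vox,) * ndim
        onehot = ndimage.gaussian_filter(onehot, sigma=sig, mode="nearest")
    total = onehot.sum(axis=0)
    onehot = onehot / np.maximum(total, 1e-12)
    # background probability removed; remaining channels sum to <= 1
    tissue = onehot[1:]

    arr = np.zeros((len(ALL_CHANNELS),) + shape, dtype=np.float32)
    arr[: len(HEALTHY_CHANNELS)] = tissue
    lab = ProbLabelMap(
        array=arr,
        channel_names=ALL_CHANNELS,
        subject_id=f"phantom-{rng_seed}",
        dataset_tag=config.dataset_tag,
    )
    lab.validate()
    return lab


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def _grow_blob(eligible: np.ndarray, seed_idx: tuple[int, ...], target: int) -> np.ndarray:
    """Grow an approximately round blob of ``target`` voxels around a seed,
    constrained to the eligible region, by taking the nearest eligible
    voxels in Euclidean distance."""
    dist = np.full(eligible.shape, np.inf)
    grids = _coordinate_grids(eligible.shape)
    d2 = sum((g - s) ** 2 for g, s in zip(grids, seed_idx))
    dist[eligible] = d2[eligible]
    flat = np.argsort(dist, axis=None, kind="stable")[:target]
    blob = np.zeros(eligible.shape, dtype=np.float32)
    keep = flat[np.isfinite(dist.flat[flat])]
    blob.flat[keep] = 1.0
    return blob


def _radius_to_voxels(radius: float, ndim: int) -> int:
    if ndim == 2:
        return max(1, int(round(np.pi * radius**2)))
    return max(1, int(round(4.0 / 3.0 * np.pi * radius**3)))


def generate_lesion_mask(
    label: ProbLabelMap,
    lesion_type: str,
    size_param: float,
    rng_seed: int,
    config: PhantomConfig | None = None,
) -> LesionMask:
    """Place a lesion in a healthy phantom.

    ``size_param`` in [0, 1] scales the target lesion radius between the
    configured bounds; the expected voxel count is non-decreasing in it.
    WMH lesions are one or more small blobs in the periventricular
    white-matter band; tumours are three concentric compartments (NE core,
    GD-enhancing ring, oedema shell) seeded inside white matter.
    """
    if lesion_type not in ("wmh", "tumour"):
        raise LabelMapError(f"unknown lesion type {lesion_type!r}")
    if not 0.0 <= size_param <= 1.0:
        raise LabelMapError("size_param must lie in [0, 1]")
    config = config or PhantomConfig(shape=label.spatial_shape)
    rng = np.random.default_rng(rng_seed)
    ndim = len(label.spatial_shape)

    r_lo, r_hi = config.lesion_radius_range
    radius = r_lo + size_param * (r_hi - r_lo)

    wm = label.channel("WM") > 0.5
    if lesion_type == "wmh":
        # periventricular band: WM within a dilated neighbourhood of the
        # DGM blobs / ventricle surrogate (the high-CSF interior region)
        interior = (label.channel("DGM") > 0.3) | (
            (label.channel("CSF") > 0.3) & ndimage.binary_erosion(label.brain_mask(), iterations=2)
        )
        band = ndimage.binary_dilation(interior, iterations=3) & wm
        if not band.any():
            band = wm  # degenerate anatomy: fall back to any WM
        if not band.any():
            raise LabelMapError("no eligible WMH placement region")
        n_blobs = int(rng.integers(1, 3))
        target_total = _radius_to_voxels(radius, ndim) * (0.5 + size_param)
        if size_param == 0.0:
            if not config.allow_min_lesion:
                raise LabelMapError("size_param=0 with allow_min_lesion=False")
            target_total, n_blobs = 1, 1
        mask = np.zeros(label.spatial_shape, dtype=np.float32)
        cand = np.argwhere(band)
        per_blob = max(1, int(round(target_total / n_blobs)))
        for _ in range(n_blobs):
            seed = tuple(cand[rng.integers(len(cand))])
            mask = np.clip(mask + _grow_blob(band, seed, per_blob), 0, 1)
        return LesionMask(layers={"WMH": mask}, lesion_type="wmh")

    # tumour: seed deep in WM, three nested compartments
    core_elig = ndimage.binary_erosion(wm, iterations=1)
    if not core_elig.any():
        core_elig = wm
    if not core_elig.any():
        raise LabelMapError("no eligible tumour placement region")
    cand = np.argwhere(core_elig)
    seed = tuple(cand[rng.integers(len(cand))])
    brain = label.brain_mask()
    if size_param == 0.0 and not config.allow_min_lesion:
        raise LabelMapError("size_param=0 with allow_min_lesion=False")
    r_core = max(radius, 1.0 if size_param > 0 else 0.6)
    grids = _coordinate_grids(label.spatial_shape)
    d = np.sqrt(sum((g - s) ** 2 for g, s in zip(grids, seed)))
    core = ((d <= r_core) & brain).astype(np.float32)
    if core.sum() == 0:
        core.flat[np.ravel_multi_index(seed, label.spatial_shape)] = 1.0
    gd = ((d <= r_core + 1.2) & brain).astype(np.float32) - core
    oed = ((d <= r_core + 1.2 + max(1.0, 0.8 * radius)) & brain).astype(np.float32) - core - gd
    mask = LesionMask(
        layers={
            "NE_tumour": core,
            "GD_tumour": np.clip(gd, 0, 1),
            "oedema": np.clip(oed, 0, 1),
        },
        lesion_type="tumour",
    )
    mask.validate()
    return mask


def fuse_lesion(label: ProbLabelMap, mask: LesionMask) -> ProbLabelMap:
    """Fuse a binary lesion mask into a probabilistic label map.

    Lesion channels are set from the mask layers and healthy channels are
    zeroed exactly where the (combined) mask is 1; all other voxels are
    unchanged.
    """
    out = label.copy()
    for name, layer in mask.layers.items():
        if name not in label.channel_names:
            raise LabelMapError(f"mask layer {name!r} not among label channels")
        if layer.shape != label.spatial_shape:
            raise LabelMapError("mask / label spatial shape mismatch")
    total = np.zeros(label.spatial_shape, dtype=np.float32)
    for name, layer in mask.layers.items():
        idx = label.channel_names.index(name)
        out.array[idx] = np.clip(out.array[idx] + layer, 0, 1)
        total = np.clip(total + layer, 0, 1)
    on = total >= 0.5
    for idx in label.healthy_indices:
        out.array[idx][on] = 0.0
    # nested tumour layers may overlap after the OR above: re-impose
    # disjointness with core > ring > shell priority
    if len(mask.layers) > 1:
        order = ["NE_tumour", "GD_tumour", "oedema"]
        claimed = np.zeros(label.spatial_shape, dtype=bool)
        for name in order:
            if name in mask.layers:
                idx = label.channel_names.index(name)
                out.array[idx][claimed] = 0.0
                claimed |= out.array[idx] >= 0.5
    return out


def superimpose_tumour_augmentation(
    healthy_labels: list[ProbLabelMap],
    tumour_labels: list[ProbLabelMap],
    n: int,
    rng_seed: int,
) -> list[ProbLabelMap]:
    """Transplant tumour masks onto healthy label maps.

    Draws ``n`` (healthy, tumour) pairs without replacement under the seed
    and fuses each tumour's binary compartments into the healthy map,
    producing maps that carry both phenotypes.  Mirrors the augmentation
    used to teach the label generator multi-pathology co-occurrence.
    """
    if n > min(len(healthy_labels), len(tumour_labels)):
        raise LabelMapError("n exceeds available subjects")
    rng = np.random.default_rng(rng_seed)
    h_idx = rng.permutation(len(healthy_labels))[:n]
    t_idx = rng.permutation(len(tumour_labels))[:n]
    out = []
    for hi, ti in zip(h_idx, t_idx):
        tum = tumour_labels[ti]
        layers = {
            name: (tum.channel(name) >= 0.5).astype(np.float32)
            for name in ("NE_tumour", "GD_tumour", "oedema")
            if name in tum.channel_names and (tum.channel(name) >= 0.5).any()
        }
        if not layers:
            raise LabelMapError(f"tumour label {tum.subject_id!r} has no tumour voxels")
        fused = fuse_lesion(healthy_labels[hi], LesionMask(layers=layers, lesion_type="tumour"))
        fused.subject_id = f"{healthy_labels[hi].subject_id}+tum{tum.subject_id}"
        out.append(fused)
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class PhantomDataset:
    """Paired phantom labels and simulated images with metadata."""

    labels: list[ProbLabelMap]
    images: dict[tuple[str, str], np.ndarray]  # (subject_id, modality) -> image
    modalities: list[str]
    config: PhantomConfig

    def slices_2d(self, min_brain_fraction: float = 0.01):
        """Yield (label_slice, {modality: image_slice}) axial slices from
        volumes, dropping background-only slices."""
        for lab in self.labels:
            if not lab.is_3d:
                yield lab, {m: self.images[(lab.subject_id, m)] for m in self.modalities}
                continue
            for k in range(lab.spatial_shape[-1]):
                sl = lab.axial_slice(k)
                frac = sl.brain_mask().mean()
                if frac < min_brain_fraction:
                    continue
                yield sl, {
                    m: self.images[(lab.subject_id, m)][..., k] for m in self.modalities
                }


def make_phantom_dataset(
    config: PhantomConfig,
    stats,
    modalities: list[str],
    bias_params=None,
) -> PhantomDataset:
    """Generate a full phantom dataset: fused labels plus one
    statistics-derived image per modality per subject."""
    from .simulator import BiasFieldParams, sd_image

    config.validate()
    bias_params = bias_params or BiasFieldParams()
    master = np.random.default_rng(config.seed)
    labels: list[ProbLabelMap] = []
    images: dict[tuple[str, str], np.ndarray] = {}
    for s in range(config.n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        lab = generate_phantom_label(config, sub_seed)
        lab.subject_id = f"{config.dataset_tag}-{s:04d}"
        rng = np.random.default_rng(sub_seed + 1)
        for kind, freq in config.lesion_frequency.items():
            if rng.random() < freq:
                mask = generate_lesion_mask(
                    lab, kind, float(rng.random()), int(rng.integers(0, 2**31 - 1)), config
                )
                lab = fuse_lesion(lab, mask)
        lab.validate()
        labels.append(lab)
        for j, m in enumerate(modalities):
            img = sd_image(
                lab, stats, m, config.dataset_tag, bias_params, rng_seed=sub_seed + 101 + j
            )
            images[(lab.subject_id, m)] = img
    return PhantomDataset(labels=labels, images=images, modalities=list(modalities), config=config)
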