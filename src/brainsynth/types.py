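"""Core containers shared across the pipeline.

The central object is :class:`ProbLabelMap`, a multi-channel probabilistic
segmentation: five healthy tissue channels (CSF, grey matter, white matter,
deep grey matter, brainstem) holding per-voxel probabilities, followed by
binary lesion channels (white-matter hyperintensities and the three tumour
compartments).  Lesions dominate: wherever a lesion channel is 1 every
healthy channel is forced to 0, so the per-voxel channel sum never
exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HEALTHY_CHANNELS = ("CSF", "GM", "WM", "DGM", "brainstem")
LESION_CHANNELS = ("WMH", "NE_tumour", "oedema", "GD_tumour")
ALL_CHANNELS = HEALTHY_CHANNELS + LESION_CHANNELS

#: threshold used whenever a probabilistic channel is counted as a mask
COUNT_THRESHOLD = 0.5

_SUM_TOL = 1e-5


class LabelMapError(ValueError):
    """Raised when a label map violates its invariants or contracts."""


@dataclass
class ProbLabelMap:
    """Multi-channel probabilistic label map, 2D slice or 3D volume.

    Parameters
    ----------
    array
        Probabilities of shape ``(C, H, W)`` or ``(C, H, W, D)`` in [0, 1].
        The axial axis is the last one for volumes.
    channel_names
        Ordered channel names, healthy tissues first then lesions.
    voxel_size_mm
        Physical voxel size, one value per spatial axis convention (3-tuple).
    subject_id, dataset_tag
        Free-form provenance strings.
    axial_index
        For 2D slices cut from a volume: the axial index of the slice.
    """

    array: np.ndarray
    channel_names: tuple[str, ...] = ALL_CHANNELS
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    dataset_tag: str = ""
    axial_index: int | None = None

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=np.float32)
        self.channel_names = tuple(self.channel_names)
        if self.array.ndim not in (3, 4):
            raise LabelMapError(
                f"label array must be (C,H,W) or (C,H,W,D), got shape {self.array.shape}"
            )
        if self.array.shape[0] != len(self.channel_names):
            raise LabelMapError(
                f"{self.array.shape[0]} channels but {len(self.channel_names)} names"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def is_3d(self) -> bool:
        return self.array.ndim == 4

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.array.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.array.shape[0]

    # -- channel bookkeeping --------------------------------------------
    @property
    def healthy_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.channel_names) if n in HEALTHY_CHANNELS]

    @property
    def lesion_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.channel_names) if n in LESION_CHANNELS]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.array[self.channel_names.index(name)]
        except ValueError as exc:
            raise LabelMapError(f"no channel named {name!r}") from exc

    def lesion_voxel_count(self, name: str) -> int:
        """Voxels of lesion ``name`` above the counting threshold."""
        if name not in LESION_CHANNELS:
            raise LabelMapError(f"{name!r} is not a lesion channel")
        return int(np.count_nonzero(self.channel(name) > COUNT_THRESHOLD))

    def brain_mask(self) -> np.ndarray:
        """Boolean mask of voxels with any tissue/lesion probability."""
        return self.array.sum(axis=0) > _SUM_TOL

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Check all invariants; raise :class:`LabelMapError` on violation."""
        a = self.array
        if not np.isfinite(a).all():
            raise LabelMapError("non-finite values in label map")
        if a.min() < 0 or a.max() > 1 + _SUM_TOL:
            raise LabelMapError("label probabilities outside [0, 1]")
        if a.sum(axis=0).max() > 1 + _SUM_TOL:
            raise LabelMapError("per-voxel channel sum exceeds 1")
        les = self.lesion_indices
        if les:
            lesion = a[les]
            binary = np.isclose(lesion, 0) | np.isclose(lesion, 1)
            if not binary.all():
                raise LabelMapError("lesion channels must be binary")
            lesion_on = lesion.max(axis=0) >= 0.5
            healthy = a[self.healthy_indices]
            if healthy[:, lesion_on].max(initial=0.0) > _SUM_TOL:
                raise LabelMapError("healthy probability under a lesion voxel")

    # -- convenience -----------------------------------------------------
    def copy(self) -> "ProbLabelMap":
        return replace(self, array=self.array.copy())

    def axial_slice(self, index: int) -> "ProbLabelMap":
        """Extract a 2D slice (axial axis = last axis) from a volume."""
        if not self.is_3d:
            raise LabelMapError("axial_slice requires a 3D label map")
        return replace(self, array=self.array[..., index].copy(), axial_index=index)


@dataclass
class LesionMask:
    """Binary lesion placement, possibly with nested tumour layers.

    ``layers`` maps lesion channel name to a binary array of the label's
    spatial shape.  Tumours use the three disjoint compartments
    (NE core, GD-enhancing ring, oedema shell); WMH uses a single layer.
    """

    layers: dict[str, np.ndarray] = field(default_factory=dict)
    lesion_type: str = ""

    def __post_init__(self) -> None:
        self.layers = {k: np.asarray(v, dtype=np.float32) for k, v in self.layers.items()}

    @property
    def total_mask(self) -> np.ndarray:
        if not self.layers:
            raise LabelMapError("empty lesion mask")
        return np.clip(sum(self.layers.values()), 0, 1)

    def validate(self) -> None:
        stack = np.stack(list(self.layers.values()))
        if not np.isin(stack, (0.0, 1.0)).all():
            raise LabelMapError("lesion layers must be binary")
        if stack.sum(axis=0).max() > 1:
            raise LabelMapError("lesion layers overlap")
        if stack.sum() == 0:
            raise LabelMapError("lesion mask has no voxels")


def renormalise_probabilities(array: np.ndarray) -> np.ndarray:
    """Rescale voxels whose channel sum exceeds 1 so the sum equals 1.

    Voxels already summing to <= 1 are untouched; used to restore the
    label-map invariant after a decoder produced free [0,1] channels.
    """
    total = array.sum(axis=0, keepdims=True)
    scale = np.where(total > 1.0, total, 1.0)
    return array / scale
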