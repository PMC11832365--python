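"""NIfTI input/output for label maps and intensity images.

Label maps are stored as 4-D NIfTI volumes (H, W, D, C) — channels on the
fourth dimension — with a JSON sidecar carrying channel names, dataset tag,
subject id and axial index; 2D slices are stored with a singleton third
axis.  Images are single-channel NIfTI.  Round trips are lossless for
float32 data and preserve the affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .types import ALL_CHANNELS, LabelMapError, ProbLabelMap

_DEFAULT_AFFINE = np.eye(4)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_label(label: ProbLabelMap, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    arr = label.array
    if label.is_3d:
        data = np.moveaxis(arr, 0, -1)  # (H, W, D, C)
    else:
        data = np.moveaxis(arr, 0, -1)[:, :, None, :]  # (H, W, 1, C)
    img = nib.Nifti1Image(data.astype(np.float32), affine if affine is not None else _DEFAULT_AFFINE)
    img.header.set_zooms(tuple(label.voxel_size_mm) + (1.0,))
    nib.save(img, str(path))
    sidecar = {
        "channel_names": list(label.channel_names),
        "dataset_tag": label.dataset_tag,
        "subject_id": label.subject_id,
        "voxel_size_mm": list(label.voxel_size_mm),
        "axial_index": label.axial_index,
        "is_3d": label.is_3d,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_label(path: str | Path) -> ProbLabelMap:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:
        raise LabelMapError(f"cannot read NIfTI label {path}: {exc}") from exc
    if data.ndim != 4:
        raise LabelMapError(f"{path}: expected 4-D label NIfTI, got shape {data.shape}")
    side_path = _sidecar_path(path)
    if side_path.exists():
        side = json.loads(side_path.read_text())
    else:
        import logging

        logging.getLogger(__name__).warning(
            "%s: missing sidecar, assuming default channel order", path
        )
        side = {"channel_names": list(ALL_CHANNELS), "is_3d": data.shape[2] > 1}
    arr = np.moveaxis(data, -1, 0)
    if not side.get("is_3d", data.shape[2] > 1):
        arr = arr[:, :, :, 0]
    return ProbLabelMap(
        array=arr,
        channel_names=tuple(side.get("channel_names", ALL_CHANNELS)),
        voxel_size_mm=tuple(side.get("voxel_size_mm", (1.0, 1.0, 1.0))),
        subject_id=side.get("subject_id", ""),
        dataset_tag=side.get("dataset_tag", ""),
        axial_index=side.get("axial_index"),
    )


def write_image(image: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    data = np.asarray(image, dtype=np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    nib.save(nib.Nifti1Image(data, affine if affine is not None else _DEFAULT_AFFINE), str(path))
    return path


def read_image(path: str | Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:
        raise LabelMapError(f"cannot read NIfTI image {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[2] == 1:
        return data[:, :, 0]
    return data
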