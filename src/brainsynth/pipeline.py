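"""End-to-end orchestration: conditioned dataset sampling, 3D volume
assembly with constant style, and real/synthetic dataset mixing.

A single master seed fans out deterministic per-component seeds, so any
pipeline product is bit-reproducible from its configuration."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .diffusion import CONDITIONING_ORDER, ConditioningVector, LabelGenerator
from .imagegen import ImageGenerator, StyleCode
from .types import LabelMapError, ProbLabelMap

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *names) -> int:
    """Deterministic per-component seed derived from the master seed and a
    component path (stable across processes; always < 2^31)."""
    h = hashlib.sha256(("/".join(map(str, names)) + f"#{master_seed}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class SamplingSpec:
    """What to sample: per-lesion conditioning (absent lesion -> P=0;
    ``"random"`` -> uniform draw within the training set's [Q1, Q3]
    proportion band; or an explicit value in [0, 1]), the style image, the
    number of samples, DDIM steps and the master seed."""

    lesions: dict[str, float | str] = field(default_factory=dict)
    modality: str = "T1"
    style_image: np.ndarray | None = None
    n_samples: int = 1
    ddim_steps: int = 200
    seed: int = 0
    slice_position: float | None = None

    def validate(self) -> None:
        if self.ddim_steps < 1:
            raise ValueError("ddim_steps must be >= 1")
        for name, v in self.lesions.items():
            if name not in CONDITIONING_ORDER:
                raise ValueError(f"unknown lesion {name!r}")
            if isinstance(v, str):
                if v != "random":
                    raise ValueError(f"lesion spec must be a value or 'random', got {v!r}")
            elif not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"explicit conditioning {name}={v} outside [0, 1]")


def draw_conditionings(
    spec: SamplingSpec, quartiles: dict[str, tuple[float, float]], rng: np.random.Generator
) -> list[ConditioningVector]:
    """Resolve a sampling spec into one conditioning vector per sample."""
    out = []
    for _ in range(spec.n_samples):
        props = {}
        for name in CONDITIONING_ORDER:
            v = spec.lesions.get(name, 0.0)
            if v == "random":
                q1, q3 = quartiles.get(name, (0.0, 0.0))
                props[name] = float(rng.uniform(q1, q3))
            else:
                props[name] = float(v)
        out.append(ConditioningVector(props, slice_position=spec.slice_position))
    return out


def sample_paired_dataset_2d(
    label_gen: LabelGenerator, image_gen: ImageGenerator, spec: SamplingSpec
) -> list[tuple[ProbLabelMap, np.ndarray]]:
    """Sample conditioned 2D labels and render each with the requested
    style image; returns (label, image) pairs."""
    spec.validate()
    if spec.style_image is None:
        raise LabelMapError("a style image is required to sample paired data")
    rng = np.random.default_rng(derive_seed(spec.seed, "cond-2d"))
    conds = draw_conditionings(spec, label_gen.cond_quartiles, rng)
    labels = label_gen.sample_labels(
        conds, n_steps=spec.ddim_steps, rng_seed=derive_seed(spec.seed, "ddim-2d")
    )
    style = image_gen.encode_style(spec.style_image, modality=spec.modality)
    pairs = []
    for lab in labels:
        img = image_gen.generate_image(lab, style)
        pairs.append((lab, img))
    return pairs


def sample_paired_volume_3d(
    label_gen: LabelGenerator,
    image_gen: ImageGenerator,
    spec: SamplingSpec,
    per_slice_styles: bool = False,
) -> tuple[ProbLabelMap, np.ndarray, list[StyleCode]]:
    """Sample one 3D label and assemble the matching volume by rendering
    each axial slice through the 2D image generator.

    The style code is computed once from the style image and reused for
    every slice (constant-style assembly keeps the contrast consistent
    between neighbouring slices).  ``per_slice_styles=True`` re-encodes the
    style from each freshly generated slice instead — the inconsistent
    variant, exposed for comparison.
    """
    spec.validate()
    if spec.style_image is None:
        raise LabelMapError("a style image is required to sample paired data")
    rng = np.random.default_rng(derive_seed(spec.seed, "cond-3d"))
    one = SamplingSpec(**{**spec.__dict__, "n_samples": 1})
    cond = draw_conditionings(one, label_gen.cond_quartiles, rng)
    label = label_gen.sample_labels(
        cond, n_steps=spec.ddim_steps, rng_seed=derive_seed(spec.seed, "ddim-3d")
    )[0]
    if not label.is_3d:
        raise LabelMapError("the label generator is 2D; volume sampling needs a 3D generator")
    style = image_gen.encode_style(spec.style_image, modality=spec.modality)
    slices, styles_used = [], []
    for k in range(label.spatial_shape[-1]):
        sl = label.axial_slice(k)
        img = image_gen.generate_image(sl, style)
        slices.append(img)
        styles_used.append(style)
        if per_slice_styles:
            style = image_gen.encode_style(img, modality=spec.modality)
    volume = np.stack(slices, axis=-1)
    return label, volume, styles_used


def mix_real_synthetic(
    real_set: list, synthetic_set: list, real_pct: float, syn_pct: float, rng_seed: int = 0
) -> list[tuple[str, object]]:
    """Mix R% of the real set with S% of the synthetic set (rounded
    half-up), seeded subsampling without replacement.  Returns a manifest
    of ("real"|"synthetic", item) entries."""
    if real_pct < 0 or syn_pct < 0 or real_pct + syn_pct == 0:
        raise ValueError("percentages must be >= 0 and not both zero")
    rng = np.random.default_rng(rng_seed)

    def take(items, pct, tag):
        n = int(np.floor(len(items) * pct / 100.0 + 0.5))
        idx = sorted(rng.permutation(len(items))[:n])
        return [(tag, items[i]) for i in idx]

    manifest = take(real_set, real_pct, "real") + take(synthetic_set, syn_pct, "synthetic")
    if not manifest:
        raise ValueError("mixing produced an empty dataset")
    return manifest
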