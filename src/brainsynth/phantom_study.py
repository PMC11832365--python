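"""The standard desk-scale phantom study.

One place defines the study conditions used by the verification suite and
the reproduction script: the phantom training corpus (about 500 32x32
slices with mixed WMH / tumour phenotypes), the training budgets of the
three models, and the evaluation draws.  Everything is a deterministic
function of a master seed.
"""

from __future__ import annotations

import numpy as np

from .autoencoder import VaeTrainConfig, train_label_vae
from .diffusion import DiffusionTrainConfig, train_label_diffusion
from .imagegen import ImageGenTrainConfig, TrainingTriplet, train_image_generator
from .phantom import PhantomConfig, fuse_lesion, generate_lesion_mask, generate_phantom_label
from .pipeline import derive_seed
from .simulator import BiasFieldParams, default_phantom_stats, normalise_image, sd_image

#: standard corpus: 500 training + 40 held-out 32x32 phantom slices
N_TRAIN = 500
N_HELD = 40
WMH_FRACTION = 0.4  # then 30% tumour, 30% healthy
STUDY_SHAPE = (32, 32)


def make_study_labels(seed: int = 0, n_total: int = N_TRAIN + N_HELD):
    """Phantom corpus with mixed phenotypes.

    Returns ``(labels, kinds)`` where kinds[i] in {"wmh", "tum", "healthy"}.
    """
    cfg = PhantomConfig(shape=STUDY_SHAPE, seed=seed)
    rng = np.random.default_rng(derive_seed(seed, "study-lesions"))
    labels, kinds = [], []
    for i in range(n_total):
        lab = generate_phantom_label(cfg, derive_seed(seed, "anatomy", i))
        r = rng.random()
        if r < WMH_FRACTION:
            lab = fuse_lesion(
                lab,
                generate_lesion_mask(
                    lab, "wmh", float(rng.random()), derive_seed(seed, "wmh", i), cfg
                ),
            )
            kinds.append("wmh")
        elif r < 0.7:
            lab = fuse_lesion(
                lab,
                generate_lesion_mask(
                    lab, "tumour", float(rng.random()), derive_seed(seed, "tum", i), cfg
                ),
            )
            kinds.append("tum")
        else:
            kinds.append("healthy")
        labels.append(lab)
    return labels, kinds


def train_study_vae(train_labels, seed: int = 0):
    """S-VAE at the study budget: 20 epochs, batch 64, default weights."""
    cfg = VaeTrainConfig(epochs=20, batch_size=64, seed=derive_seed(seed, "vae"))
    cfg.model.seed = cfg.seed
    return train_label_vae(train_labels, cfg)


def train_study_ldm(vae, train_labels, seed: int = 0, tag: str = "ldm"):
    """Conditioned LDM at the study budget (150 epochs, width-48 denoiser)."""
    return train_label_diffusion(
        vae, train_labels, DiffusionTrainConfig(seed=derive_seed(seed, tag))
    )


def make_style_triplets(
    seed: int = 0,
    n_phantoms: int = 130,
    modalities=("T1", "FLAIR"),
    n_train: int = 220,
):
    """Training triplets for the image generator: phantom slices rendered
    in two SD contrasts, style image from an independent phantom of the
    same contrast.  Returns ``(train, held)``."""
    cfg = PhantomConfig(shape=STUDY_SHAPE)
    stats = default_phantom_stats(modalities=modalities)
    bp = BiasFieldParams()
    trips = []
    for i in range(n_phantoms):
        lab = generate_phantom_label(cfg, derive_seed(seed, "ig-content", i))
        lab2 = generate_phantom_label(cfg, derive_seed(seed, "ig-style", i))
        for j, mod in enumerate(modalities):
            trips.append(
                TrainingTriplet(
                    m=lab.array,
                    i=normalise_image(
                        sd_image(lab, stats, mod, "phantom", bp,
                                 rng_seed=derive_seed(seed, "ig-img", i, j))
                    ),
                    i_s=normalise_image(
                        sd_image(lab2, stats, mod, "phantom", bp,
                                 rng_seed=derive_seed(seed, "ig-sty", i, j))
                    ),
                    modality=mod,
                )
            )
    return trips[:n_train], trips[n_train:]


def train_study_image_generator(triplets, seed: int = 0, ablated: bool = False):
    """Image generator at the study budget; ``ablated`` drops the
    contrastive loss and uses paired styles (the ablation arm)."""
    cfg = ImageGenTrainConfig(seed=derive_seed(seed, "imagegen", int(ablated)))
    if ablated:
        cfg.lambda_cont = 0.0
        cfg.unpaired_styles = False
    cfg.model.seed = cfg.seed
    return train_image_generator(triplets, cfg)
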