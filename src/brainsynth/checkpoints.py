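"""Checkpointing: models are stored as .npz archives whose entries are the
flat parameter state plus a JSON metadata string (config, seeds, schedule),
so a checkpoint fully determines the sampling behaviour."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np


def _pack(prefix: str, state: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {f"{prefix}{k}": v for k, v in state.items()}


def _unpack(prefix: str, arrays) -> dict[str, np.ndarray]:
    plen = len(prefix)
    return {k[plen:]: arrays[k] for k in arrays.files if k.startswith(prefix)}


def save_vae(model, path: str | Path) -> Path:
    path = Path(path)
    meta = {"kind": "label_vae", "config": asdict(model.config)}
    np.savez(path, __meta__=json.dumps(meta), **_pack("vae.", model.state_dict()))
    return path


def load_vae(path: str | Path):
    from .autoencoder import LabelVAE, VaeConfig

    arrays = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(arrays["__meta__"]))
    if meta.get("kind") != "label_vae":
        raise ValueError(f"{path} is not a label-VAE checkpoint")
    model = LabelVAE(VaeConfig(**{**meta["config"], "seed": meta["config"].get("seed", 0)}))
    model.load_state_dict(_unpack("vae.", arrays))
    model.eval()
    return model


def save_label_generator(gen, path: str | Path) -> Path:
    from .diffusion import CONDITIONING_ORDER

    path = Path(path)
    meta = {
        "kind": "label_generator",
        "vae_config": asdict(gen.vae.config),
        "denoiser_config": asdict(gen.denoiser.config),
        "T": gen.schedule.T,
        "latent_std": gen.latent_std,
        "latent_shape": list(gen.latent_shape),
        "with_slice": gen.with_slice,
        "cond_quartiles": {k: list(v) for k, v in gen.cond_quartiles.items()},
        "conditioning_order": list(CONDITIONING_ORDER),
    }
    np.savez(
        path,
        __meta__=json.dumps(meta),
        betas=gen.schedule.betas,
        **_pack("vae.", gen.vae.state_dict()),
        **_pack("den.", gen.denoiser.state_dict()),
    )
    return path


def load_label_generator(path: str | Path):
    from .autoencoder import LabelVAE, VaeConfig
    from .diffusion import CondUNet, DenoiserConfig, LabelGenerator, NoiseSchedule

    arrays = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(arrays["__meta__"]))
    if meta.get("kind") != "label_generator":
        raise ValueError(f"{path} is not a label-generator checkpoint")
    vae = LabelVAE(VaeConfig(**meta["vae_config"]))
    vae.load_state_dict(_unpack("vae.", arrays))
    vae.eval()
    den = CondUNet(DenoiserConfig(**meta["denoiser_config"]))
    den.load_state_dict(_unpack("den.", arrays))
    den.eval()
    betas = arrays["betas"]
    alphas = 1.0 - betas
    schedule = NoiseSchedule(
        T=meta["T"], betas=betas, alphas=alphas, alpha_bars=np.cumprod(alphas)
    )
    return LabelGenerator(
        vae=vae,
        denoiser=den,
        schedule=schedule,
        latent_std=meta["latent_std"],
        latent_shape=tuple(meta["latent_shape"]),
        with_slice=meta["with_slice"],
        cond_quartiles={k: tuple(v) for k, v in meta["cond_quartiles"].items()},
    )


def save_image_generator(model, path: str | Path) -> Path:
    path = Path(path)
    cfg = asdict(model.cfg)
    cfg["modalities"] = list(cfg["modalities"])
    meta = {"kind": "image_generator", "config": cfg}
    np.savez(path, __meta__=json.dumps(meta), **_pack("ig.", model.state_dict()))
    return path


def load_image_generator(path: str | Path):
    from .imagegen import ImageGenConfig, ImageGenerator

    arrays = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(arrays["__meta__"]))
    if meta.get("kind") != "image_generator":
        raise ValueError(f"{path} is not an image-generator checkpoint")
    cfg = meta["config"]
    cfg["modalities"] = tuple(cfg["modalities"])
    model = ImageGenerator(ImageGenConfig(**cfg))
    model.load_state_dict(_unpack("ig.", arrays))
    model.eval()
    return model
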