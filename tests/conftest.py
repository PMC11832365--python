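import numpy as np
import pytest

from brainsynth.phantom import (
    PhantomConfig,
    fuse_lesion,
    generate_lesion_mask,
    generate_phantom_label,
)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(shape=(32, 32), seed=0)


@pytest.fixture(scope="session")
def healthy_label(phantom_config):
    return generate_phantom_label(phantom_config, rng_seed=42)


@pytest.fixture(scope="session")
def wmh_label(phantom_config, healthy_label):
    mask = generate_lesion_mask(healthy_label, "wmh", 0.7, rng_seed=7, config=phantom_config)
    return fuse_lesion(healthy_label, mask)


@pytest.fixture(scope="session")
def tumour_label(phantom_config, healthy_label):
    mask = generate_lesion_mask(healthy_label, "tumour", 0.6, rng_seed=9, config=phantom_config)
    return fuse_lesion(healthy_label, mask)


@pytest.fixture(scope="session")
def small_label_set(phantom_config):
    """A small mixed set of phantom labels (healthy / WMH / tumour)."""
    rng = np.random.default_rng(123)
    labels = []
    for i in range(24):
        lab = generate_phantom_label(phantom_config, rng_seed=500 + i)
        r = rng.random()
        if r < 0.4:
            lab = fuse_lesion(
                lab, generate_lesion_mask(lab, "wmh", float(rng.random()), 900 + i, phantom_config)
            )
        elif r < 0.7:
            lab = fuse_lesion(
                lab,
                generate_lesion_mask(lab, "tumour", float(rng.random()), 900 + i, phantom_config),
            )
        labels.append(lab)
    return labels
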