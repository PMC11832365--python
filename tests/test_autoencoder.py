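import numpy as np
import pytest

from brainsynth import nn
from brainsynth.autoencoder import (
    LabelVAE,
    PatchDiscriminator,
    RandomFeatureExtractor,
    VaeConfig,
    VaeLossWeights,
    VaeTrainConfig,
    focal_recon_loss,
    gaussian_kld,
    noise_robust_loss,
    perceptual_loss,
    train_label_vae,
    vae_total_loss,
)
from brainsynth.nn import Tensor
from brainsynth.types import LabelMapError


def brute_force_focal(l, p, gamma, alpha, eps=1e-6):
    """Independent per-pixel summation of the focal reconstruction loss."""
    total = 0.0
    for li, pi in zip(l.ravel(), p.ravel()):
        pc = min(max(pi, eps), 1 - eps)
        tc = min(max(li, eps), 1 - eps)
        ce = -(tc * np.log(pc) + (1 - tc) * np.log(1 - pc))
        ent = -(tc * np.log(tc) + (1 - tc) * np.log(1 - tc))
        w = ((pi - li) ** 2 + eps**2) ** (gamma / 2)
        a = 2.0 * (alpha * tc + (1 - alpha) * (1 - tc))
        total += w * a * (ce - ent)
    return total / l.size


class TestFocalLoss:
    def test_perfect_reconstruction_is_zero(self):
        rng = np.random.default_rng(0)
        l = rng.random((2, 3, 3))
        assert focal_recon_loss(l, l.copy()).item() < 1e-6

    def test_matches_bruteforce_on_toy_pair(self):
        rng = np.random.default_rng(1)
        l = rng.random((1, 3, 3))
        p = rng.random((1, 3, 3))
        got = focal_recon_loss(l, p, gamma=0.3, alpha=0.9).item()
        assert got == pytest.approx(brute_force_focal(l, p, 0.3, 0.9), abs=1e-9)

    def test_gamma_zero_reduces_to_base_loss(self):
        rng = np.random.default_rng(2)
        l = (rng.random((1, 4, 4)) > 0.5).astype(float)
        p = rng.random((1, 4, 4))
        got = focal_recon_loss(l, p, gamma=1e-12, alpha=0.5).item()
        # base loss: unweighted binary KL per pixel
        assert got == pytest.approx(brute_force_focal(l, p, 1e-12, 0.5), abs=1e-9)

    def test_nan_input_rejected(self):
        l = np.zeros((1, 2, 2))
        p = np.full((1, 2, 2), np.nan)
        with pytest.raises(LabelMapError):
            focal_recon_loss(l, p)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(LabelMapError):
            focal_recon_loss(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


class TestKld:
    def test_standard_normal_posterior_is_zero(self):
        z = np.zeros((2, 3, 4, 4))
        assert gaussian_kld(z, z, reduction="sum").item() == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        mu = rng.normal(size=(2, 5))
        lv = rng.normal(size=(2, 5))
        expect = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1)
        assert gaussian_kld(mu, lv, reduction="sum").item() == pytest.approx(expect, abs=1e-9)


@pytest.fixture(scope="module")
def vae():
    return LabelVAE(VaeConfig(width=8, seed=0))


class TestVaeModel:

    def test_latent_compression_ratio(self, vae, healthy_label):
        z = vae.encode(healthy_label)
        assert z.mean.shape == (3, 8, 8)  # 2 downsamplings of 32x32, 3 channels
        assert z.downsampling == 4

    def test_eval_mode_sample_equals_mean(self, vae, healthy_label):
        vae.eval()
        z = vae.encode(healthy_label)
        assert np.array_equal(z.z, z.mean)

    def test_train_mode_sampling_is_seeded(self, vae, healthy_label):
        vae.train()
        z1 = vae.encode(healthy_label, rng_seed=5)
        z2 = vae.encode(healthy_label, rng_seed=5)
        assert np.array_equal(z1.z, z2.z)
        vae.eval()

    def test_indivisible_shape_rejected(self, vae):
        from brainsynth.types import ProbLabelMap

        bad = ProbLabelMap(array=np.zeros((9, 30, 30), dtype=np.float32))
        with pytest.raises(LabelMapError, match="pad"):
            vae.encode(bad)

    def test_decode_respects_bounds_for_any_latent(self, vae):
        rng = np.random.default_rng(0)
        for scale in (0.1, 1.0, 10.0):
            out = vae.decode(rng.normal(0, scale, (3, 8, 8)).astype(np.float32))
            assert out.array.min() >= 0 and out.array.max() <= 1
            assert out.array.sum(axis=0).max() <= 1 + 1e-5

    def test_latent_channel_mismatch_rejected(self, vae):
        with pytest.raises(LabelMapError):
            vae.decode(np.zeros((5, 8, 8), dtype=np.float32))


class TestTotalLoss:
    def test_breakdown_sums_to_total(self, healthy_label):
        vae = LabelVAE(VaeConfig(width=8, seed=1))
        disc = PatchDiscriminator(9, width=8, seed=2)
        extractor = RandomFeatureExtractor(9)
        l = Tensor(healthy_label.array[None])
        total, terms = vae_total_loss(vae, l, VaeLossWeights(), extractor, disc, rng_seed=0)
        assert total.item() == pytest.approx(sum(t.item() for t in terms.values()), abs=1e-9)
        assert set(terms) == {"kld", "focal", "noise_robust", "perceptual", "adversarial"}

    def test_all_zero_weights_give_zero(self, healthy_label):
        vae = LabelVAE(VaeConfig(width=8, seed=1))
        zero = VaeLossWeights(kld=0, perceptual=0, adversarial=0, focal=0, noise_robust=0)
        total, _ = vae_total_loss(vae, Tensor(healthy_label.array[None]), zero, None, None)
        assert total.item() == 0.0

    def test_negative_weight_rejected(self, healthy_label):
        vae = LabelVAE(VaeConfig(width=8, seed=1))
        bad = VaeLossWeights(kld=-1.0)
        with pytest.raises(ValueError):
            vae_total_loss(vae, Tensor(healthy_label.array[None]), bad, None, None)

    def test_noise_robust_sigma_zero_equals_focal_of_decode(self, healthy_label):
        vae = LabelVAE(VaeConfig(width=8, seed=1))
        l = Tensor(healthy_label.array[None])
        mean, _ = vae.encode_tensor(l)
        z = mean.detach()
        a = noise_robust_loss(vae, l, z, 0.0, rng_seed=0).item()
        b = focal_recon_loss(l, vae.decode_tensor(z)).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_noise_robust_grows_with_sigma(self, healthy_label):
        vae = LabelVAE(VaeConfig(width=8, seed=1))
        l = Tensor(healthy_label.array[None])
        mean, _ = vae.encode_tensor(l)
        z = mean.detach()
        small = np.mean([noise_robust_loss(vae, l, z, 0.05, s).item() for s in range(100)])
        big = np.mean([noise_robust_loss(vae, l, z, 0.5, s).item() for s in range(100)])
        assert big >= small


class TestPerceptual:
    def test_identical_inputs_zero(self, healthy_label):
        ex = RandomFeatureExtractor(9)
        x = Tensor(healthy_label.array[None])
        assert perceptual_loss(x, x, ex).item() == pytest.approx(0.0, abs=1e-9)


class TestTraining:
    def test_one_epoch_is_deterministic(self, small_label_set):
        cfg = VaeTrainConfig(epochs=1, batch_size=8, seed=11, model=VaeConfig(width=8, seed=11))
        m1, h1 = train_label_vae(small_label_set, cfg)
        m2, h2 = train_label_vae(small_label_set, cfg)
        assert h1[-1]["total"] == h2[-1]["total"]
        for (k1, p1), (k2, p2) in zip(
            sorted(m1.state_dict().items()), sorted(m2.state_dict().items())
        ):
            assert k1 == k2 and np.array_equal(p1, p2)

    def test_empty_dataset_rejected(self):
        with pytest.raises(LabelMapError):
            train_label_vae([], VaeTrainConfig())

    def test_loss_decreases_over_short_training(self, small_label_set):
        cfg = VaeTrainConfig(epochs=4, batch_size=8, seed=0, model=VaeConfig(width=8))
        _, hist = train_label_vae(small_label_set, cfg)
        assert hist[-1]["total"] < hist[0]["total"]
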