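import numpy as np
import pytest

from brainsynth.imagegen import (
    ImageGenConfig,
    ImageGenerator,
    PixelPlusRandomExtractor,
    SchedulerState,
    TrainingTriplet,
    contrastive_style_loss,
    cosine_similarity,
    discriminator_accuracy,
    discriminator_input,
    feature_matching_loss,
    hinge_gan_loss,
    make_training_triplet,
    modality_dataset_disc_loss,
    perceptual_loss,
    random_affine,
    scheduler_step,
)
from brainsynth.nn import Tensor
from brainsynth.phantom import PhantomConfig, generate_phantom_label
from brainsynth.types import LabelMapError


class TestHingeLoss:
    def test_separated_scores_give_zero_disc_loss(self):
        real = Tensor(np.full((1, 1, 4, 4), 1.5))
        fake = Tensor(np.full((1, 1, 4, 4), -1.5))
        assert hinge_gan_loss(real, fake, "discriminator").item() == 0.0

    def test_generator_loss_at_zero_scores_is_zero(self):
        fake = Tensor(np.zeros((1, 1, 4, 4)))
        assert hinge_gan_loss(None, fake, "generator").item() == 0.0

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=(1, 1, 3, 3))
        f = rng.normal(size=(1, 1, 3, 3))
        got = hinge_gan_loss(Tensor(r), Tensor(f), "discriminator").item()
        expect = np.maximum(0, 1 - r).mean() + np.maximum(0, 1 + f).mean()
        assert got == pytest.approx(expect, abs=1e-9)
        got_g = hinge_gan_loss(None, Tensor(f), "generator").item()
        assert got_g == pytest.approx(-f.mean(), abs=1e-9)

    def test_multi_scale_sums(self):
        f = Tensor(np.ones((1, 1, 2, 2)))
        got = hinge_gan_loss(None, [f, f], "generator").item()
        assert got == pytest.approx(-2.0, abs=1e-9)


class TestFeatureMatching:
    def test_identical_features_zero(self):
        f = [[Tensor(np.ones((1, 2, 4, 4)))]]
        assert feature_matching_loss(f, f).item() == 0.0

    def test_single_scale_single_feature_is_plain_l1(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(1, 2, 4, 4))
        b = rng.normal(size=(1, 2, 4, 4))
        got = feature_matching_loss([[Tensor(a)]], [[Tensor(b)]]).item()
        assert got == pytest.approx(np.abs(a - b).mean(), abs=1e-9)

    def test_double_sum_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        real = [[Tensor(rng.normal(size=(1, 2, 3, 3))) for _ in range(2)] for _ in range(2)]
        fake = [[Tensor(rng.normal(size=(1, 2, 3, 3))) for _ in range(2)] for _ in range(2)]
        got = feature_matching_loss(real, fake).item()
        expect = sum(
            np.abs(r.data - f.data).mean()
            for rl, fl in zip(real, fake)
            for r, f in zip(rl, fl)
        )
        assert got == pytest.approx(expect, abs=1e-9)

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            feature_matching_loss([[Tensor(np.ones((1, 1, 2, 2)))]], [])


class _IdentityExtractor:
    def features(self, x):
        return [x]


class TestPerceptual:
    def test_identity_extractor_equals_l1(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(1, 1, 4, 4))
        b = rng.normal(size=(1, 1, 4, 4))
        got = perceptual_loss(Tensor(a), Tensor(b), _IdentityExtractor()).item()
        assert got == pytest.approx(np.abs(a - b).mean(), abs=1e-9)

    def test_layerwise_sum_matches_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        b = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        ex = PixelPlusRandomExtractor(seed=0)
        got = perceptual_loss(Tensor(a), Tensor(b), ex).item()
        expect = sum(
            np.abs(fa.data - fb.data).mean()
            for fa, fb in zip(ex.features(Tensor(a)), ex.features(Tensor(b)))
        )
        assert got == pytest.approx(expect, rel=1e-6)


class TestContrastive:
    def test_identity_augmentation_gives_zero(self):
        cfg = ImageGenConfig(width=8, seed=0)
        model = ImageGenerator(cfg)
        model.eval()
        imgs = np.random.default_rng(0).random((2, 32, 32)).astype(np.float32)
        loss = contrastive_style_loss(model.encoder, imgs, lambda im, rng: im, 0)
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_antiparallel_codes_give_two(self):
        a = Tensor(np.array([[1.0, 0.0]]))
        b = Tensor(np.array([[-1.0, 0.0]]))
        assert (1.0 - cosine_similarity(a, b)).item() == pytest.approx(2.0, abs=1e-9)

    def test_matches_direct_dot_product(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 16))
        b = rng.normal(size=(3, 16))
        got = cosine_similarity(Tensor(a), Tensor(b)).item()
        expect = np.mean(
            [np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)) for x, y in zip(a, b)]
        )
        assert got == pytest.approx(expect, rel=1e-9)

    def test_zero_norm_code_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(Tensor(np.zeros((1, 4))), Tensor(np.ones((1, 4))))

    def test_affine_augmentation_preserves_range(self):
        rng = np.random.default_rng(6)
        img = rng.random((32, 32)).astype(np.float32)
        aug = random_affine(img, rng)
        assert aug.shape == img.shape
        assert aug.min() >= img.min() - 1e-5 and aug.max() <= img.max() + 1e-5
        assert not np.allclose(aug, img)


class _PerfectClassifier:
    def __init__(self, mod_logits, dat_logits):
        self.m, self.d = mod_logits, dat_logits

    def __call__(self, x):
        return Tensor(self.m), Tensor(self.d)


class TestModalityDatasetLoss:
    def test_disabled_by_default_weights(self):
        loss = modality_dataset_disc_loss(None, np.zeros((1, 32, 32)), None, None, 0.0, 0.0)
        assert loss.item() == 0.0

    def test_missing_classifier_fails_when_enabled(self):
        with pytest.raises(ValueError):
            modality_dataset_disc_loss(None, np.zeros((1, 32, 32)), None, None, 1.0, 0.0)

    def test_confident_correct_predictions_near_zero(self):
        onehot = np.array([[1.0, 0.0]])
        clf = _PerfectClassifier(np.array([[20.0, -20.0]]), np.array([[20.0, -20.0]]))
        loss = modality_dataset_disc_loss(clf, np.zeros((1, 32, 32)), onehot, onehot, 1.0, 1.0)
        assert loss.item() < 1e-5  # clamp floor of the stabilised BCE

    def test_matches_bce_oracle(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(2, 3))
        onehot = np.eye(3)[:2]
        clf = _PerfectClassifier(logits, logits)
        got = modality_dataset_disc_loss(clf, np.zeros((2, 32, 32)), onehot, onehot, 0.7, 0.3).item()
        p = np.clip(1 / (1 + np.exp(-logits)), 1e-6, 1 - 1e-6)
        bce = -(onehot * np.log(p) + (1 - onehot) * np.log(1 - p)).mean()
        assert got == pytest.approx((0.7 + 0.3) * bce, rel=1e-6)


class TestScheduler:
    @pytest.mark.parametrize(
        "mean_acc,expect",
        [
            (0.5, (False, True)),
            (0.6, (True, True)),
            (0.7, (True, True)),
            (0.75, (True, True)),
            (0.8, (True, False)),
        ],
    )
    def test_truth_table(self, mean_acc, expect):
        state = SchedulerState(window=[mean_acc] * 19)
        train_g, train_d, _ = scheduler_step(state, mean_acc)
        assert (train_g, train_d) == expect

    def test_window_is_bounded_and_rolling(self):
        state = SchedulerState()
        for i in range(30):
            _, _, state = scheduler_step(state, 0.5)
        assert len(state.window) == 20

    def test_short_window_uses_available_entries(self):
        state = SchedulerState()
        train_g, train_d, state = scheduler_step(state, 0.9)
        assert (train_g, train_d) == (True, False)

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            scheduler_step(SchedulerState(), 1.2)

    def test_accuracy_definition(self):
        real = [Tensor(np.array([[[[1.0, -1.0]]]]))]  # one of two patches correct
        fake = [Tensor(np.array([[[[-1.0, -1.0]]]]))]  # both correct
        assert discriminator_accuracy(real, fake) == pytest.approx(0.75)


class TestDiscriminatorInput:
    def test_channel_counting_and_order(self):
        img = np.zeros((2, 1, 16, 16))
        lab = np.ones((2, 9, 16, 16))
        onehot = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        stacked = discriminator_input(img, lab, onehot)
        assert stacked.shape == (2, 13, 16, 16)
        # order: image, labels, modality planes (constant-valued)
        assert np.allclose(stacked.data[:, 0], 0.0)
        assert np.allclose(stacked.data[:, 1:10], 1.0)
        assert np.allclose(stacked.data[0, 10], 1.0) and np.allclose(stacked.data[0, 11], 0.0)
        assert stacked.data[1, 11].std() == 0.0  # broadcast plane is constant


@pytest.fixture(scope="module")
def volume():
    cfg = PhantomConfig(shape=(32, 32, 12), softness_vox=1.0)
    lab = generate_phantom_label(cfg, rng_seed=2)
    img = np.random.default_rng(0).random(lab.spatial_shape).astype(np.float32)
    return lab, img


class TestTriplets:

    def test_style_slice_always_differs(self, volume):
        lab, img = volume
        for seed in range(100):
            t = make_training_triplet(lab, img, "T1", seed)
            assert t.style_slice_index != t.slice_index
            assert t.modality == "T1"

    def test_2d_label_rejected(self, healthy_label):
        with pytest.raises(LabelMapError):
            make_training_triplet(healthy_label, np.zeros((32, 32)), "T1", 0)

    def test_style_code_contract(self):
        model = ImageGenerator(ImageGenConfig(width=8, seed=0))
        model.eval()
        img = np.random.default_rng(1).random((32, 32)).astype(np.float32)
        c1 = model.encode_style(img)
        c2 = model.encode_style(img)
        assert len(c1.s) == 16
        assert np.array_equal(c1.s, c2.s)  # eval mode is deterministic

    def test_generate_image_contract(self, healthy_label):
        model = ImageGenerator(ImageGenConfig(width=8, seed=0))
        model.eval()
        style = model.encode_style(np.zeros((32, 32), dtype=np.float32))
        img = model.generate_image(healthy_label, style)
        assert img.shape == (32, 32)
        assert img.min() >= 0.0 and img.max() <= 1.0
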