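import numpy as np
import pytest
from scipy.stats import spearmanr

from brainsynth.phantom import (
    PhantomConfig,
    fuse_lesion,
    generate_lesion_mask,
    generate_phantom_label,
    make_phantom_dataset,
    superimpose_tumour_augmentation,
)
from brainsynth.simulator import default_phantom_stats
from brainsynth.types import HEALTHY_CHANNELS, LabelMapError, LesionMask


class TestPhantomAnatomy:
    def test_invariants_hold(self, healthy_label):
        healthy_label.validate()
        assert healthy_label.array.sum(axis=0).max() <= 1 + 1e-5

    def test_all_five_regions_present(self, healthy_label):
        for region in HEALTHY_CHANNELS:
            assert (healthy_label.channel(region) > 0.5).sum() > 0, region

    def test_boundaries_are_fractional(self, healthy_label):
        frac = (healthy_label.array > 0.05) & (healthy_label.array < 0.95)
        assert frac.sum() > 100  # smoothing must produce genuinely soft borders

    def test_same_seed_is_bit_identical(self, phantom_config):
        a = generate_phantom_label(phantom_config, rng_seed=3)
        b = generate_phantom_label(phantom_config, rng_seed=3)
        assert np.array_equal(a.array, b.array)

    def test_different_seeds_differ(self, phantom_config):
        a = generate_phantom_label(phantom_config, rng_seed=1)
        b = generate_phantom_label(phantom_config, rng_seed=2)
        wa = a.channel("WM") > 0.5
        wb = b.channel("WM") > 0.5
        dice = 2 * (wa & wb).sum() / (wa.sum() + wb.sum())
        assert dice < 1.0

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom_label(PhantomConfig(shape=(8, 8)), rng_seed=0)

    def test_3d_phantom_valid(self):
        cfg = PhantomConfig(shape=(32, 32, 24), softness_vox=1.0)
        lab = generate_phantom_label(cfg, rng_seed=11)
        lab.validate()
        assert lab.is_3d
        for region in HEALTHY_CHANNELS:
            assert (lab.channel(region) > 0.5).sum() > 0, region


class TestLesions:
    def test_wmh_sits_in_white_matter(self, healthy_label, phantom_config):
        mask = generate_lesion_mask(healthy_label, "wmh", 0.5, 5, phantom_config)
        wm = healthy_label.channel("WM") > 0.5
        inside = mask.total_mask.astype(bool) & wm
        assert inside.sum() / mask.total_mask.sum() > 0.9

    def test_tumour_layers_disjoint(self, healthy_label, phantom_config):
        mask = generate_lesion_mask(healthy_label, "tumour", 0.7, 5, phantom_config)
        stack = np.stack(list(mask.layers.values()))
        assert stack.sum(axis=0).max() <= 1
        assert all(layer.sum() > 0 for layer in mask.layers.values())

    def test_size_zero_policy(self, healthy_label):
        cfg_min = PhantomConfig(shape=(32, 32), allow_min_lesion=True)
        mask = generate_lesion_mask(healthy_label, "wmh", 0.0, 5, cfg_min)
        assert mask.total_mask.sum() >= 1
        cfg_strict = PhantomConfig(shape=(32, 32), allow_min_lesion=False)
        with pytest.raises(LabelMapError):
            generate_lesion_mask(healthy_label, "wmh", 0.0, 5, cfg_strict)

    def test_unknown_lesion_type_rejected(self, healthy_label):
        with pytest.raises(LabelMapError):
            generate_lesion_mask(healthy_label, "gliosis", 0.5, 1)

    @pytest.mark.parametrize("lesion_type", ["wmh", "tumour"])
    def test_mean_size_monotone_in_size_param(self, healthy_label, phantom_config, lesion_type):
        params = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for sp in params:
            counts = [
                generate_lesion_mask(healthy_label, lesion_type, sp, seed, phantom_config)
                .total_mask.sum()
                for seed in range(100)
            ]
            means.append(np.mean(counts))
        rho, p = spearmanr(params, means)
        assert rho > 0 and p < 0.01
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestFusion:
    def test_empty_region_is_identity(self, healthy_label):
        mask = LesionMask(layers={"WMH": np.zeros(healthy_label.spatial_shape)})
        fused = fuse_lesion(healthy_label, mask)
        assert np.array_equal(fused.array, healthy_label.array)

    def test_all_ones_mask_zeroes_all_healthy(self, healthy_label):
        mask = LesionMask(layers={"WMH": np.ones(healthy_label.spatial_shape)})
        fused = fuse_lesion(healthy_label, mask)
        for region in HEALTHY_CHANNELS:
            assert fused.channel(region).max() == 0.0

    def test_single_voxel_mask_changes_only_that_voxel(self, healthy_label):
        m = np.zeros(healthy_label.spatial_shape)
        m[16, 16] = 1.0
        fused = fuse_lesion(healthy_label, LesionMask(layers={"WMH": m}))
        diff = np.abs(fused.array - healthy_label.array).sum(axis=0) > 0
        assert diff[16, 16]
        diff[16, 16] = False
        assert not diff.any()

    def test_never_increases_channel_sum(self, healthy_label, phantom_config):
        mask = generate_lesion_mask(healthy_label, "tumour", 0.8, 3, phantom_config)
        fused = fuse_lesion(healthy_label, mask)
        assert (
            fused.array.sum(axis=0) <= healthy_label.array.sum(axis=0) + 1e-5 + 1.0
        ).all()  # lesion voxels go to exactly 1
        fused.validate()

    def test_channel_name_mismatch_rejected(self, healthy_label):
        mask = LesionMask(layers={"not_a_channel": np.ones(healthy_label.spatial_shape)})
        with pytest.raises(LabelMapError):
            fuse_lesion(healthy_label, mask)


class TestAugmentationAndDataset:
    def test_superimpose_fifty_maps_counts_and_invariants(self, phantom_config):
        """Transplanting tumour masks onto 50 healthy subjects yields 50
        new maps carrying both phenotypes, drawn without replacement."""
        cfg = phantom_config
        rng = np.random.default_rng(0)
        healthy = [generate_phantom_label(cfg, s) for s in range(50)]
        tumours = []
        for s in range(50):
            lab = generate_phantom_label(cfg, 100 + s)
            tumours.append(
                fuse_lesion(
                    lab,
                    generate_lesion_mask(lab, "tumour", float(rng.random()), 200 + s, cfg),
                )
            )
        out = superimpose_tumour_augmentation(healthy, tumours, n=50, rng_seed=1)
        assert len(out) == 50
        for lab in out:
            lab.validate()
            assert lab.lesion_voxel_count("NE_tumour") > 0
        # pairing without replacement: all source subjects distinct
        assert len({lab.subject_id for lab in out}) == 50
        assert superimpose_tumour_augmentation(healthy, tumours, 0, 1) == []
        with pytest.raises(LabelMapError):
            superimpose_tumour_augmentation(healthy, tumours, 51, 1)

    def test_dataset_counts_and_finiteness(self):
        cfg = PhantomConfig(shape=(32, 32), n_subjects=5, seed=3, lesion_frequency={"wmh": 1.0})
        stats = default_phantom_stats()
        ds = make_phantom_dataset(cfg, stats, ["T1", "FLAIR"])
        assert len(ds.labels) == 5
        assert len(ds.images) == 10
        for img in ds.images.values():
            assert np.isfinite(img).all() and img.min() >= 0
        assert all(lab.lesion_voxel_count("WMH") > 0 for lab in ds.labels)

    def test_lesion_frequency_zero_gives_healthy_only(self):
        cfg = PhantomConfig(shape=(32, 32), n_subjects=4, seed=3)
        ds = make_phantom_dataset(cfg, default_phantom_stats(), ["T1"])
        for lab in ds.labels:
            assert all(lab.lesion_voxel_count(c) == 0 for c in ("WMH", "NE_tumour"))

    def test_3d_slicing_drops_background(self):
        cfg = PhantomConfig(shape=(32, 32, 24), n_subjects=2, seed=1, softness_vox=1.0)
        ds = make_phantom_dataset(cfg, default_phantom_stats(), ["T1"])
        slices = list(ds.slices_2d())
        assert slices
        for lab, imgs in slices:
            assert lab.axial_index is not None
            assert lab.brain_mask().mean() >= 0.01
            assert imgs["T1"].shape == lab.spatial_shape
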