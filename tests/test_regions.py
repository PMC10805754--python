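"""Region delineation: thresholds, label partition, recovery on phantoms."""

import numpy as np
import pytest

from angiolume.phantom import PhantomSpec, generate_vessel_tree, render_channels
from angiolume.preprocess import PreprocessParams, preprocess_bundle
from angiolume.regions import (
    RegionLabel,
    RegionParams,
    classify_regions,
    combine_tumor_masks,
    hypoxia_threshold,
    hypoxic_fraction,
    tumor_from_reporter,
    tumor_from_vessel_morphology,
)
from angiolume.volume import ImageVolume


def _vol(data, spacing=(1, 1, 1)):
    return ImageVolume(np.asarray(data, float), spacing, "reporter")


class TestHypoxiaThreshold:
    def test_direct_formula(self):
        rng = np.random.default_rng(0)
        # healthy sample with exact mean 100, sd 20
        vals = rng.normal(size=4096)
        vals = (vals - vals.mean()) / vals.std() * 20.0 + 100.0
        data = vals.reshape(16, 16, 16)
        thr = hypoxia_threshold(_vol(data), np.ones(data.shape, bool), RegionParams(sigma_factor=1.5))
        assert thr == pytest.approx(130.0, abs=1e-9)

    def test_constant_signal(self):
        thr = hypoxia_threshold(_vol(np.full((8, 8, 8), 7.0)), np.ones((8, 8, 8), bool))
        assert thr == pytest.approx(7.0)

    def test_monte_carlo_matches_population(self):
        rng = np.random.default_rng(1)
        data = rng.normal(50.0, 5.0, size=(64, 64, 64))
        thr = hypoxia_threshold(_vol(data), np.ones(data.shape, bool), RegionParams(sigma_factor=1.5))
        assert thr == pytest.approx(50.0 + 1.5 * 5.0, rel=0.01)

    def test_empty_healthy_mask_raises(self):
        with pytest.raises(ValueError):
            hypoxia_threshold(_vol(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))


class TestClassification:
    def test_no_hypoxia_below_threshold(self):
        tumor = np.zeros((8, 8, 8), bool)
        tumor[2:6, 2:6, 2:6] = True
        reporter = _vol(np.full((8, 8, 8), 1.0))
        regions = classify_regions(tumor, reporter, threshold=5.0)
        assert regions.mask(RegionLabel.HYPOXIC_TUMOR).sum() == 0
        assert regions.mask(RegionLabel.NORMOXIC_TUMOR).sum() == tumor.sum()

    def test_labels_partition_volume(self):
        rng = np.random.default_rng(2)
        tumor = rng.uniform(size=(10, 10, 10)) > 0.6
        excluded = rng.uniform(size=(10, 10, 10)) > 0.9
        reporter = _vol(rng.uniform(size=(10, 10, 10)))
        regions = classify_regions(tumor, reporter, threshold=0.5, excluded=excluded)
        counts = np.bincount(regions.labels.ravel(), minlength=5)
        assert counts.sum() == 1000

    def test_sigma_monotonicity(self):
        rng = np.random.default_rng(3)
        tumor = np.ones((12, 12, 12), bool)
        reporter = _vol(rng.uniform(size=(12, 12, 12)))
        healthy = np.ones((12, 12, 12), bool)
        counts = []
        for sf in (0.5, 1.5, 3.0):
            thr = hypoxia_threshold(reporter, healthy, RegionParams(sigma_factor=sf))
            regions = classify_regions(tumor, reporter, thr)
            counts.append(regions.mask(RegionLabel.HYPOXIC_TUMOR).sum())
        assert counts[0] >= counts[1] >= counts[2]


class TestTumorMasks:
    def test_reporter_all_zero_empty(self):
        assert not tumor_from_reporter(_vol(np.zeros((16, 16, 16)))).any()

    def test_threshold_above_max_empty(self):
        params = RegionParams(reporter_tumor_threshold=100.0)
        assert not tumor_from_reporter(_vol(np.random.default_rng(0).uniform(size=(16, 16, 16))), params).any()

    def test_phantom_tumor_covered_when_baseline_above_threshold(self):
        spec = PhantomSpec(shape=(24, 64, 64), spacing=(1, 1, 1), n_vessels=6,
                           tumor_fraction=0.25, af_density=0,
                           reporter_tumor_baseline=0.4, seed=13)
        truth = generate_vessel_tree(spec)
        ch = render_channels(truth, spec)
        mask = tumor_from_reporter(ch.reporter, RegionParams(reporter_tumor_threshold=0.25))
        covered = (mask & truth.tumor_mask).sum() / truth.tumor_mask.sum()
        assert covered >= 0.9

    def test_combine_union_and_removal(self):
        a = np.zeros((6, 6, 6), bool); a[0] = True
        b = np.zeros((6, 6, 6), bool); b[1] = True
        out = combine_tumor_masks(a, b)
        assert out.sum() == a.sum() + b.sum()
        assert out.sum() <= a.sum() + b.sum()
        out2 = combine_tumor_masks(a, b, manual_remove=np.ones((6, 6, 6), bool))
        assert out2.sum() == 0

    def test_combine_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combine_tumor_masks(np.zeros((4, 4, 4), bool), np.zeros((5, 4, 4), bool))

    def test_missing_model_raises_with_guidance(self):
        with pytest.raises(ValueError, match="reporter"):
            tumor_from_vessel_morphology(_vol(np.zeros((8, 8, 8))), None)


class TestRecovery:
    def test_hypoxic_fraction_recovered_to_5_points(self):
        # generative hypoxic fraction 0.6; reporter modes separated far
        # beyond 4 healthy-sd
        spec = PhantomSpec(shape=(24, 72, 72), spacing=(1, 1, 1), n_vessels=6,
                           tumor_fraction=0.25, radius_range_tumor=(3.0, 5.0),
                           tumor_vessel_boost=1.0, hypoxic_fraction_target=0.6,
                           af_density=0, noise_sd=0.02, bias_field_amplitude=0.0,
                           seed=17)
        truth = generate_vessel_tree(spec)
        true_frac = truth.hypoxic_mask.sum() / truth.tumor_mask.sum()
        assert true_frac == pytest.approx(0.6, abs=0.02)

        ch = render_channels(truth, spec)
        pp = PreprocessParams(k=8, peak_sd_factor=0.2)
        _, reporter_c, excl = preprocess_bundle(ch.vessel, ch.autofluorescence, ch.reporter, pp)
        healthy = ~truth.tumor_mask & ~excl
        thr = hypoxia_threshold(reporter_c, healthy)
        regions = classify_regions(truth.tumor_mask, reporter_c, thr, excluded=excl)
        recovered = hypoxic_fraction(regions)
        assert recovered == pytest.approx(true_frac, abs=0.05)


class TestTumorModel:
    def test_morphology_model_segments_phantom_tumor(self):
        """Tumor U-Net trained on downscaled vessel channels of phantoms with
        caliber/tortuosity contrast recovers held-out tumor masks."""
        from angiolume.regions import _downscale
        from angiolume.segmentation import TrainingConfig, UNet3D, train

        def make(seed):
            spec = PhantomSpec(shape=(16, 32, 32), spacing=(1, 1, 1), n_vessels=6,
                               radius_range_healthy=(1.5, 2.5), radius_range_tumor=(4, 7),
                               tumor_fraction=0.35, tortuosity_tumor=0.4, af_density=0,
                               bias_field_amplitude=0.0, tumor_vessel_boost=3.0, seed=seed)
            truth = generate_vessel_tree(spec)
            ch = render_channels(truth, spec)
            img = _downscale(ch.vessel.data, 2)
            gt = _downscale(truth.tumor_mask.astype(float), 2) > 0.5
            return img, gt, spec, truth, ch

        chunks = [make(s)[:2] for s in range(30, 38)]
        cfg = TrainingConfig(chunk_size=8, epochs=10, lr=1e-3, warmup_epochs=2,
                             base_channels=4, levels=2, seed=5)
        model = UNet3D(4, 2, seed=5)
        model, log = train(model, chunks, cfg, loss="bce")
        assert log.epoch_losses[-1] < log.epoch_losses[0]

        img, gt, spec, truth, ch = make(99)
        mask = tumor_from_vessel_morphology(ch.vessel, model, RegionParams(tumor_downscale=2))
        inter = (mask & truth.tumor_mask).sum()
        dice = 2 * inter / (mask.sum() + truth.tumor_mask.sum())
        assert dice > 0.5
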