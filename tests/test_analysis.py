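"""Segment-region assignment, lumen weighting, and the statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from angiolume.analysis import (
    assign_segments,
    freedman_diaconis_bins,
    hypoxia_ratio,
    lumen_weighted_histogram,
    significance_stars,
    vascularization_index,
    weighted_ks_test,
    welch_t_test,
)
from angiolume.phantom import Centerline, _paint_tubes
from angiolume.regions import RegionLabel, RegionLabelVolume
from angiolume.vesselgraph import extract_graph


def _regions_volume(shape=(48, 48, 96), spacing=(1.0, 1.0, 1.0), split_z=48):
    """healthy in the front half, normoxic tumor in the back half."""
    labels = np.full(shape, int(RegionLabel.HEALTHY), np.uint8)
    labels[:, :, split_z:] = int(RegionLabel.NORMOXIC_TUMOR)
    return RegionLabelVolume(labels, spacing)


class TestAssignment:
    def _graph(self):
        def line(p0, p1, n=60):
            t = np.linspace(0, 1, n)[:, None]
            return np.asarray(p0, float) + t * (np.asarray(p1, float) - np.asarray(p0, float))

        cls = [
            Centerline(line([24, 16, 10], [24, 16, 40]), np.full(60, 3.0)),   # healthy side
            Centerline(line([24, 32, 55], [24, 32, 85]), np.full(60, 3.0)),   # tumor side
        ]
        mask = _paint_tubes((48, 48, 96), (1, 1, 1), cls)
        return extract_graph(mask, (1, 1, 1))

    def test_segments_labeled_by_endpoint_region(self):
        g = self._graph()
        table = assign_segments(g, _regions_volume(), animal_id="a1")
        assert set(table["region"]) == {"healthy", "normoxic"}

    def test_lumen_weights_sum_to_one(self):
        table = assign_segments(self._graph(), _regions_volume())
        assert table["lumen_weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_border_touching_segment_excluded(self):
        def line(p0, p1, n=80):
            t = np.linspace(0, 1, n)[:, None]
            return np.asarray(p0, float) + t * (np.asarray(p1, float) - np.asarray(p0, float))

        # tube running into the x border
        cl = Centerline(line([24, 24, 40], [24, 24, 95.5]), np.full(80, 3.0))
        mask = _paint_tubes((48, 48, 96), (1, 1, 1), [cl])
        g = extract_graph(mask, (1, 1, 1))
        table = assign_segments(g, _regions_volume())
        assert len(table) == 0

    def test_frame_mismatch_raises(self):
        g = self._graph()
        bad = RegionLabelVolume(np.zeros((10, 10, 10), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            assign_segments(g, bad)

    def test_phantom_region_recovery(self, small_phantom):
        from angiolume.vesselgraph import to_isotropic

        spec, truth, _ = small_phantom
        iso, sp = to_isotropic(truth.vessel_mask, spec.spacing)
        factor = iso.shape[0] // truth.vessel_mask.shape[0]
        labels = np.full(iso.shape, int(RegionLabel.HEALTHY), np.uint8)
        tumor_iso = np.repeat(truth.tumor_mask, factor, axis=0)
        labels[tumor_iso] = int(RegionLabel.NORMOXIC_TUMOR)
        regions = RegionLabelVolume(labels, sp)
        g = extract_graph(iso, sp)
        table = assign_segments(g, regions)
        # unambiguous ground truth: a segment whose centerline is entirely on
        # one side must carry that side's label
        correct = total = 0
        for s in g.segments:
            row = table[table["segment_id"] == s.id]
            if len(row) != 1 or s.features is None:
                continue
            vox = np.minimum((s.centerline_um / np.asarray(sp)).astype(int), np.asarray(iso.shape) - 1)
            in_tumor = tumor_iso[tuple(vox.T)]
            if in_tumor.all():
                total += 1
                correct += int(row["region"].iloc[0] == "normoxic")
            elif not in_tumor.any():
                total += 1
                correct += int(row["region"].iloc[0] == "healthy")
        assert total > 0
        assert correct / total >= 0.95


class TestHistogram:
    def _table(self, volumes, values):
        w = np.asarray(volumes, float)
        return pd.DataFrame(
            {"avg_radius": values, "voxel_count": volumes, "lumen_weight": w / w.sum()}
        )

    def test_single_segment_single_bin(self):
        hist, _ = lumen_weighted_histogram(self._table([10], [2.0]), "avg_radius", bins=[0, 1, 3, 5])
        assert hist.tolist() == [0.0, 100.0, 0.0]

    def test_volume_weighting_75_25(self):
        hist, _ = lumen_weighted_histogram(
            self._table([300, 100], [1.5, 3.5]), "avg_radius", bins=[1, 2, 3, 4]
        )
        assert hist[0] == pytest.approx(75.0)
        assert hist[2] == pytest.approx(25.0)

    def test_unit_volumes_reduce_to_relative_frequency(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, 50)
        table = self._table(np.ones(50), vals)
        bins = np.linspace(0, 10, 6)
        hist, _ = lumen_weighted_histogram(table, "avg_radius", bins)
        ref, _ = np.histogram(vals, bins)
        assert np.allclose(hist, 100.0 * ref / ref.sum())

    def test_bars_sum_to_100(self):
        rng = np.random.default_rng(1)
        table = self._table(rng.integers(1, 100, 30), rng.uniform(0, 5, 30))
        hist, _ = lumen_weighted_histogram(table, "avg_radius", bins=np.linspace(0, 5, 8))
        assert hist.sum() == pytest.approx(100.0)

    def test_fd_bins_cover_data(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 1, 200)
        edges = freedman_diaconis_bins(vals)
        assert edges[0] <= vals.min() and edges[-1] >= vals.max()


class TestIndices:
    def test_vascularization_index_direct(self):
        labels = np.full((100, 100, 100), int(RegionLabel.NORMOXIC_TUMOR), np.uint8)
        regions = RegionLabelVolume(labels, (10.0, 10.0, 5.0))  # 0.5 mm³ total
        table = pd.DataFrame({"region": ["normoxic"] * 50})
        assert vascularization_index(table, regions, "normoxic") == pytest.approx(100.0)

    def test_no_segments_zero(self):
        labels = np.full((10, 10, 10), int(RegionLabel.HYPOXIC_TUMOR), np.uint8)
        regions = RegionLabelVolume(labels, (100.0, 100.0, 100.0))
        assert vascularization_index(pd.DataFrame(), regions, "hypoxic") == 0.0

    def test_zero_volume_region_raises(self):
        regions = RegionLabelVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(ValueError):
            vascularization_index(pd.DataFrame(), regions, "hypoxic")

    def test_hypoxia_ratio(self):
        assert hypoxia_ratio(1.0, 1.0) == 1.0
        assert hypoxia_ratio(2.0, 1.0) == 2.0  # a 2/3-hypoxic tumor
        assert hypoxia_ratio(0.0, 1.0) == 0.0
        assert np.isnan(hypoxia_ratio(1.0, 0.0))


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and res.stars == "ns"

    def test_matches_reference_to_1e10(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10

    def test_satterthwaite_df_matches_reference(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 3, 17)
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(res.p - ref.pvalue) < 1e-10

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_type_one_error_calibrated(self):
        """Under the null with equal variances the rejection rate at α=0.05
        is ≈0.05 over 10,000 replicates."""
        rng = np.random.default_rng(12345)
        n, reps = 10, 10000
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        se2 = va / n + vb / n
        t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
        # the vectorized replication is cross-checked against the scalar
        # implementation on a handful of draws
        for i in range(5):
            res = welch_t_test(a[i], b[i])
            assert res.p == pytest.approx(p[i], abs=1e-12)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestWeightedKS:
    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        res = weighted_ks_test(x, x)
        assert res.D == 0.0

    def test_unit_weights_match_reference(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        b = rng.normal(0.3, 1.2, size=80)
        res = weighted_ks_test(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert abs(res.D - ref.statistic) < 1e-10

    def test_shifted_uniform_D_half(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(0.5, 1.5, 1000)
        res = weighted_ks_test(a, b)
        assert res.D == pytest.approx(0.5, abs=0.06)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=30), rng.normal(size=40)
        wa = rng.uniform(0.5, 2.0, 30)
        r1 = weighted_ks_test(a, b, wa, None)
        r2 = weighted_ks_test(a, b, 10 * wa, None)
        assert r1.D == pytest.approx(r2.D, abs=1e-14)
        assert r1.p == pytest.approx(r2.p, abs=1e-14)

    def test_zero_weights_raise(self):
        with pytest.raises(ValueError):
            weighted_ks_test([1.0], [2.0], [0.0], [1.0])

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=20)
            b = rng.normal(rng.uniform(-1, 1), 1, size=25)
            res = weighted_ks_test(a, b, rng.uniform(0.1, 1, 20), rng.uniform(0.1, 1, 25))
            assert 0.0 <= res.p <= 1.0
            assert res.stars in {"ns", "*", "**", "***"}


def test_stars_convention():
    assert significance_stars(0.2) == "ns"
    assert significance_stars(0.05) == "*"
    assert significance_stars(0.01) == "**"
    assert significance_stars(0.001) == "***"
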