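"""Segmentation and intensity-score tests: exact constructions, invariances,
and recovery against the generator's ground truth."""

import numpy as np
import pandas as pd
import pytest

from condenskit import condensate_quant as cq
from condenskit import synthetic_data as syn
from condenskit.condensate_quant import LabelMask


def _disk_image(value=300.0, background=100.0, radius=8, size=64):
    yy, xx = np.mgrid[0:size, 0:size]
    disk = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= radius**2
    img = np.full((size, size), background)
    img[disk] = value
    return img, disk


class TestSegmentIntensity:
    def test_noise_free_disk_segmented_exactly(self):
        img, disk = _disk_image()
        mask = cq.segment_intensity(
            img, method="otsu", smoothing_sd_px=0.0, pixel_size_um=0.1
        )
        np.testing.assert_array_equal(mask.labels > 0, disk)
        assert mask.n_objects == 1

    def test_min_area_filter_removes_small_objects(self):
        img, disk = _disk_image(radius=3)
        area_um2 = disk.sum() * 0.01
        mask = cq.segment_intensity(
            img, smoothing_sd_px=0.0, min_area_um2=2 * area_um2, pixel_size_um=0.1
        )
        assert mask.n_objects == 0

    def test_uniform_image_yields_empty_mask(self):
        mask = cq.segment_intensity(
            np.full((32, 32), 7.0), smoothing_sd_px=0.0, pixel_size_um=0.1
        )
        assert mask.n_objects == 0

    def test_segmentation_jaccard_on_noisy_field(self):
        p = syn.FieldSimParams(
            n_condensates=20, enrichment=3.0, background=100.0,
            poisson_noise=True, seed=8,
        )
        sim = syn.render_condensate_field(p)  # SNR = 300/sqrt(400) = 15
        mask = cq.segment_intensity(
            sim.stack, min_area_um2=0.1, smoothing_sd_px=1.0
        )
        for lab in range(1, 21):
            truth = sim.label_mask == lab
            seg_labels = np.unique(mask.labels[truth])
            seg_labels = seg_labels[seg_labels > 0]
            assert seg_labels.size == 1
            seg = mask.labels == seg_labels[0]
            jaccard = (truth & seg).sum() / (truth | seg).sum()
            assert jaccard >= 0.9


class TestSegmentCellsPhase:
    def test_cell_count_exact_on_noise_free_input(self):
        sim = syn.render_cell_population(
            syn.PopulationSimParams(n_cells=25, noise_sd=0.0, seed=1)
        )
        mask = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
        assert mask.n_objects == 25

    def test_recall_at_default_noise(self):
        sim = syn.render_cell_population(
            syn.PopulationSimParams(n_cells=40, noise_sd=5.0, seed=2)
        )
        mask = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
        hit = 0
        for lab in range(1, 41):
            truth = sim.cell_mask == lab
            overlap = mask.labels[truth]
            if (overlap > 0).mean() > 0.5:
                hit += 1
        assert hit / 40 >= 0.95


class TestEnrichmentScores:
    def test_uniform_image_scores_zero(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[4:10, 4:10] = 1
        mask = LabelMask(labels, 0.1, {})
        table = cq.enrichment_scores(np.full((32, 32), 55.0), mask)
        assert table["enrichment"].iloc[0] == pytest.approx(0.0)

    def test_enrichment_arithmetic(self):
        img, disk = _disk_image(value=300.0, background=100.0)
        mask = LabelMask(disk.astype(int), 0.1, {})
        table = cq.enrichment_scores(img, mask)
        assert table["enrichment"].iloc[0] == pytest.approx(2.0)

    def test_scale_invariance_and_offset_shift(self):
        img, disk = _disk_image()
        mask = LabelMask(disk.astype(int), 0.1, {})
        e = cq.enrichment_scores(img, mask)["enrichment"].iloc[0]
        e_scaled = cq.enrichment_scores(img * 3.7, mask)["enrichment"].iloc[0]
        assert e_scaled == pytest.approx(e, rel=1e-12)
        # additive offset shrinks E predictably: E' = E * b / (b + c)
        c = 50.0
        e_offset = cq.enrichment_scores(img + c, mask)["enrichment"].iloc[0]
        assert e_offset == pytest.approx(e * 100.0 / 150.0, rel=1e-12)

    def test_relabeling_stability(self):
        p = syn.FieldSimParams(n_condensates=10, poisson_noise=False, seed=3)
        sim = syn.render_condensate_field(p)
        mask = LabelMask(sim.label_mask, 0.1, {})
        t1 = cq.enrichment_scores(sim.stack, mask)
        # reverse the label order
        relabeled = np.where(
            sim.label_mask > 0, 11 - sim.label_mask, 0
        )
        t2 = cq.enrichment_scores(sim.stack, LabelMask(relabeled, 0.1, {}))
        assert sorted(np.round(t1["enrichment"], 12)) == sorted(
            np.round(t2["enrichment"], 12)
        )

    def test_nonpositive_background_rejected(self):
        img, disk = _disk_image(background=0.0)
        with pytest.raises(ValueError, match="offset"):
            cq.enrichment_scores(img, LabelMask(disk.astype(int), 0.1, {}))


class TestClusterToDiffuseRatio:
    def test_uniform_cell_gets_zero_ratio_flagged(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:15, 5:15] = 1
        table = cq.cluster_to_diffuse_ratio(
            np.full((20, 20), 100.0), LabelMask(labels, 0.1, {}),
            smoothing_sd_px=0.0,
        )
        assert table["ratio"].iloc[0] == 0.0
        assert not table["has_cluster"].iloc[0]

    def test_ratio_arithmetic_with_fixed_threshold(self):
        labels = np.zeros((10, 20), dtype=int)
        labels[2:8, 2:18] = 1
        img = np.full((10, 20), 0.0)
        img[labels == 1] = 100.0
        img[4:6, 4:6] = 500.0  # cluster: 4 px inside a 96-px cell
        table = cq.cluster_to_diffuse_ratio(
            img, LabelMask(labels, 0.1, {}), cluster_method="fixed",
            cluster_level=250.0, smoothing_sd_px=0.0,
        )
        cell = labels == 1
        expected = (500.0 - 100.0) / img[cell].mean()
        assert table["ratio"].iloc[0] == pytest.approx(expected)

    def test_population_ratio_monotone_in_cluster_fold(self):
        medians = []
        for fold in (2.0, 5.0, 10.0):
            sim = syn.render_cell_population(
                syn.PopulationSimParams(
                    n_cells=40, cluster_fold=fold, noise_sd=2.0, seed=9
                )
            )
            cells = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
            table = cq.cluster_to_diffuse_ratio(sim.fluorescence, cells)
            medians.append(table["ratio"].median())
        assert medians[0] < medians[1] < medians[2]


class TestCrossChannelQuant:
    def test_identical_target_matches_single_channel_ratio(self):
        sim = syn.render_cell_population(
            syn.PopulationSimParams(n_cells=10, noise_sd=0.0, seed=4)
        )
        cells = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
        fluor = sim.fluorescence
        t1 = cq.cluster_to_diffuse_ratio(fluor, cells)
        t2 = cq.cross_channel_quant(fluor, fluor, cells)
        np.testing.assert_allclose(t2["ratio"], t1["ratio"], rtol=1e-12)

    def test_uniform_target_scores_zero(self):
        sim = syn.render_cell_population(
            syn.PopulationSimParams(n_cells=5, noise_sd=0.0, seed=4)
        )
        cells = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
        uniform = np.full(sim.fluorescence.pixels.shape[-2:], 80.0)
        table = cq.cross_channel_quant(sim.fluorescence, uniform, cells)
        np.testing.assert_allclose(table["ratio"], 0.0, atol=1e-12)

    def test_colocalized_channels_track_co_enrichment(self):
        # target channel = scaled mask channel: R_target = scale-invariant,
        # so it must match the mask channel's R within 10%
        sim = syn.render_cell_population(
            syn.PopulationSimParams(n_cells=20, noise_sd=1.0, seed=5)
        )
        cells = cq.segment_cells_phase(sim.phase, min_area_um2=0.5)
        target = sim.fluorescence.frame(0) * 0.6
        t_mask = cq.cluster_to_diffuse_ratio(sim.fluorescence, cells)
        t_cross = cq.cross_channel_quant(sim.fluorescence, target, cells)
        ok = t_mask["has_cluster"]
        ratio_err = np.abs(
            t_cross.loc[ok, "ratio"] - t_mask.loc[ok, "ratio"]
        ) / t_mask.loc[ok, "ratio"]
        assert ratio_err.max() < 0.10

    def test_shape_mismatch_rejected(self):
        labels = np.ones((8, 8), dtype=int)
        with pytest.raises(ValueError, match="shape"):
            cq.cross_channel_quant(
                np.ones((8, 8)), np.ones((9, 9)), LabelMask(labels, 0.1, {})
            )


class TestCountSubclusters:
    def _demix_sim(self, k_dist, seed=4, n=30):
        return syn.render_demixed_condensates(
            k_dist,
            spot_sd_um=0.15,
            separation_um=0.5,
            params=syn.FieldSimParams(
                image_size=(256, 256), n_condensates=n,
                radius_range_um=(0.6, 0.9), poisson_noise=False,
                read_noise_sd=1.0, seed=seed,
            ),
        )

    def test_single_spot_per_condensate_gives_zero_fraction(self):
        sim = self._demix_sim({1: 1.0})
        res = cq.count_subclusters(
            sim.stack.frame(0, 1), LabelMask(sim.label_mask, 0.1, {}),
            smoothing_sd_px=0.5, min_separation_um=0.4,
        )
        assert (res.counts["k"] == 1).all()
        assert res.fraction_multi == 0.0

    def test_rotation_and_scale_invariance(self):
        sim = self._demix_sim({1: 0.5, 2: 0.5}, seed=6)
        img = sim.stack.frame(0, 1)
        mask = LabelMask(sim.label_mask, 0.1, {})
        res = cq.count_subclusters(img, mask, smoothing_sd_px=0.5)
        res_rot = cq.count_subclusters(
            np.rot90(img).copy(), LabelMask(np.rot90(sim.label_mask).copy(), 0.1, {}),
            smoothing_sd_px=0.5,
        )
        np.testing.assert_array_equal(
            res.counts["k"].to_numpy(), res_rot.counts["k"].to_numpy()
        )
        res_scaled = cq.count_subclusters(img * 2.5, mask, smoothing_sd_px=0.5)
        np.testing.assert_array_equal(
            res.counts["k"].to_numpy(), res_scaled.counts["k"].to_numpy()
        )

    def test_min_size_filter_uses_area_equivalent_diameter(self):
        sim = self._demix_sim({1: 1.0}, seed=7)
        mask = LabelMask(sim.label_mask, 0.1, {})
        res_all = cq.count_subclusters(sim.stack.frame(0, 1), mask)
        res_big = cq.count_subclusters(
            sim.stack.frame(0, 1), mask, min_size_um=1.5
        )
        diam = 2 * np.sqrt(
            np.bincount(sim.label_mask.ravel())[1:] * 0.01 / np.pi
        )
        assert res_big.n == int((diam >= 1.5).sum())
        assert res_all.n == 30


class TestLeakageFraction:
    def test_fivefold_threshold_arithmetic(self):
        pct, (lo, hi) = cq.leakage_fraction(
            [100, 110, 600], reference_population=[90, 100, 105],
            fold_threshold=5.0,
        )
        assert pct == pytest.approx(100 / 3)
        assert lo < pct < hi

    def test_all_below_threshold_gives_zero(self):
        pct, _ = cq.leakage_fraction([100, 200], [100, 100], fold_threshold=5.0)
        assert pct == 0.0

    def test_recovers_configured_leaky_subpopulation(self):
        rng = np.random.default_rng(12)
        n = 1000
        leaky = rng.random(n) < 0.08
        intensities = rng.normal(100, 10, size=n)
        intensities[leaky] *= 10.0  # 10-fold brighter
        pct, _ = cq.leakage_fraction(intensities, rng.normal(100, 10, size=500))
        p_true = leaky.mean()
        half_width = 1.96 * np.sqrt(p_true * (1 - p_true) / n) * 100
        assert abs(pct - 100 * p_true) <= half_width
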