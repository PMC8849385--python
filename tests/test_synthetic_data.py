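"""Ground-truth generator tests: determinism, analytic expectations, moments."""

import numpy as np
import pytest

from condenskit import synthetic_data as syn


class TestSimulateTrajectories:
    def test_mean_squared_displacement_matches_brownian_moment(self):
        # pooled 1-frame squared displacement has mean 4 D dt in 2D (sigma=0)
        p = syn.DiffusionSimParams(
            d_coeffs=(0.01,),
            n_tracks=2000,
            track_length=10,
            sigma_loc_um=0.0,
            frame_interval=0.02,
            seed=11,
        )
        sim = syn.simulate_trajectories(p)
        steps = np.diff(sim.true_positions, axis=1)
        u = np.sum(steps**2, axis=2).ravel()
        expected = 4 * 0.01 * 0.02
        se = u.std(ddof=1) / np.sqrt(u.size)
        assert abs(u.mean() - expected) < 3 * se

    def test_localization_error_inflates_displacements_as_predicted(self):
        # reported MSD(1) = 2*dims*D*dt + 2*dims*sigma^2 at large n
        p = syn.DiffusionSimParams(
            d_coeffs=(0.005,),
            n_tracks=10_000,
            track_length=5,
            sigma_loc_um=0.03,
            frame_interval=0.02,
            seed=3,
        )
        sim = syn.simulate_trajectories(p)
        df = sim.trajectories.data
        xy = df[["x_um", "y_um"]].to_numpy().reshape(10_000, 5, 2)
        u = np.sum(np.diff(xy, axis=1) ** 2, axis=2).ravel()
        expected = 4 * 0.005 * 0.02 + 4 * 0.03**2
        se = u.std(ddof=1) / np.sqrt(u.size)
        assert abs(u.mean() - expected) < 3 * se

    def test_confined_true_positions_stay_inside_sphere(self):
        p = syn.DiffusionSimParams(
            d_coeffs=(0.05,),
            n_tracks=200,
            track_length=20,
            sigma_loc_um=0.0,
            confinement=syn.SphereConfinement(center=(1.0, 1.0), radius=0.5),
            seed=5,
        )
        sim = syn.simulate_trajectories(p)
        r = np.linalg.norm(sim.true_positions - np.array([1.0, 1.0]), axis=2)
        assert np.all(r <= 0.5 + 1e-12)

    def test_same_seed_gives_bit_identical_tables(self):
        p = syn.DiffusionSimParams(n_tracks=50, track_length=6, seed=42)
        a = syn.simulate_trajectories(p)
        b = syn.simulate_trajectories(p)
        assert a.trajectories.data.equals(b.trajectories.data)
        np.testing.assert_array_equal(a.component_labels, b.component_labels)

    def test_component_fractions_respected(self):
        p = syn.DiffusionSimParams(
            d_coeffs=(0.001, 0.05),
            fractions=(0.3, 0.7),
            n_tracks=5000,
            track_length=2,
            seed=9,
        )
        sim = syn.simulate_trajectories(p)
        frac = np.mean(sim.component_labels == 0)
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 5000)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.DiffusionSimParams(fractions=(0.5, 0.4), d_coeffs=(0.01, 0.02))
        with pytest.raises(ValueError):
            syn.DiffusionSimParams(track_length=1)


class TestRenderCondensateField:
    def test_noise_free_render_equals_expected_image(self):
        p = syn.FieldSimParams(
            n_condensates=5,
            background=100.0,
            enrichment=2.0,
            poisson_noise=False,
            read_noise_sd=0.0,
            seed=0,
        )
        sim = syn.render_condensate_field(p)
        img = sim.stack.frame(0)
        assert np.all(img[sim.label_mask > 0] == 300.0)
        assert np.all(img[sim.label_mask == 0] == 100.0)

    def test_null_field_has_uniform_expectation(self):
        p = syn.FieldSimParams(
            n_condensates=5, enrichment=0.0, poisson_noise=False, seed=1
        )
        sim = syn.render_condensate_field(p)
        assert np.ptp(sim.stack.frame(0)) == 0.0

    def test_truth_mask_recovers_configured_enrichment(self):
        from condenskit.condensate_quant import LabelMask, enrichment_scores

        p = syn.FieldSimParams(
            n_condensates=50, enrichment=3.0, poisson_noise=True, seed=2
        )
        sim = syn.render_condensate_field(p)
        mask = LabelMask(sim.label_mask, p.pixel_size_um, {})
        table = enrichment_scores(sim.stack, mask)
        assert abs(table["enrichment"].mean() - 3.0) / 3.0 < 0.05

    def test_determinism(self):
        p = syn.FieldSimParams(n_condensates=10, seed=7)
        a = syn.render_condensate_field(p)
        b = syn.render_condensate_field(p)
        np.testing.assert_array_equal(a.stack.pixels, b.stack.pixels)
        np.testing.assert_array_equal(a.label_mask, b.label_mask)

    def test_overcrowded_field_raises(self):
        p = syn.FieldSimParams(
            image_size=(64, 64),
            n_condensates=80,
            radius_range_um=(0.5, 0.6),
            max_place_tries=20,
            seed=0,
        )
        with pytest.raises(RuntimeError, match="place"):
            syn.render_condensate_field(p)


class TestSimulateFrapMovie:
    def test_full_bleach_full_recovery_trace_shape(self):
        p = syn.FrapSimParams(
            bleach_depth=1.0,
            mobile_fraction=1.0,
            fade_rate=0.0,
            noise_sd=0.0,
            recovery_time_s=10.0,
        )
        trace = syn.expected_frap_trace(p)
        t = np.arange(p.n_frames) * p.frame_interval
        assert np.all(trace[: p.bleach_frame] == p.prebleach_level)
        assert trace[p.bleach_frame] == 0.0
        expected = p.prebleach_level * (1 - np.exp(-(t[-1] - 3.0) / 10.0))
        assert trace[-1] == pytest.approx(expected)

    def test_no_bleach_no_fade_gives_flat_movie(self):
        p = syn.FrapSimParams(bleach_depth=0.0, fade_rate=0.0, noise_sd=0.0)
        sim = syn.simulate_frap_movie(p)
        movie = sim.stack.pixels[:, 0]
        assert np.ptp(movie, axis=0).max() == 0.0

    def test_roi_roles_present_and_disjoint_from_background(self):
        sim = syn.simulate_frap_movie(syn.FrapSimParams())
        shape = sim.stack.pixels.shape[-2:]
        for role in ("bleached", "control", "whole_condensate", "background"):
            assert sim.rois.role_mask(role, shape).any()
        bg = sim.rois.role_mask("background", shape)
        whole = sim.rois.role_mask("whole_condensate", shape)
        assert not (bg & whole).any()

    def test_bleach_frame_validation(self):
        with pytest.raises(ValueError):
            syn.FrapSimParams(bleach_frame=100, n_frames=100)


class TestRenderCellPopulation:
    def test_filamentous_fraction_sampled_correctly(self):
        lengths = syn.sample_cell_lengths(2000, filamentous_fraction=0.3, seed=13)
        frac = np.mean(lengths > 4.0)
        # body ~2.2 um << 4, filamentous ~8 um >> 4: threshold isolates p_f
        assert abs(frac - 0.3) < 1.96 * np.sqrt(0.3 * 0.7 / 2000)

    def test_cluster_peak_equals_fold_times_diffuse(self):
        p = syn.PopulationSimParams(
            n_cells=3, cluster_fold=5.0, diffuse_level=100.0, noise_sd=0.0, seed=2
        )
        sim = syn.render_cell_population(p)
        img = sim.fluorescence.frame(0)
        assert img.max() == pytest.approx(500.0, rel=0.01)

    def test_same_seed_identical_images(self):
        p = syn.PopulationSimParams(n_cells=20, noise_sd=2.0, seed=6)
        a = syn.render_cell_population(p)
        b = syn.render_cell_population(p)
        np.testing.assert_array_equal(a.phase.pixels, b.phase.pixels)
        np.testing.assert_array_equal(a.fluorescence.pixels, b.fluorescence.pixels)

    def test_truth_table_matches_mask(self):
        p = syn.PopulationSimParams(n_cells=15, seed=3)
        sim = syn.render_cell_population(p)
        assert len(sim.table) == 15
        assert sim.cell_mask.max() == 15

    def test_too_small_field_raises(self):
        p = syn.PopulationSimParams(n_cells=50, image_size=(20, 20), seed=0)
        with pytest.raises(ValueError, match="too small"):
            syn.render_cell_population(p)


class TestRenderDemixedCondensates:
    def _params(self, **kw):
        defaults = dict(
            image_size=(256, 256),
            n_condensates=30,
            radius_range_um=(0.6, 0.9),
            poisson_noise=False,
            read_noise_sd=0.0,
            seed=4,
        )
        defaults.update(kw)
        return syn.FieldSimParams(**defaults)

    def test_all_single_spots_yield_zero_demixing(self):
        sim = syn.render_demixed_condensates(
            {1: 1.0}, spot_sd_um=0.15, separation_um=0.5, params=self._params()
        )
        assert (sim.table["k_true"] == 1).all()

    def test_two_spot_construction_counts_exactly(self):
        from condenskit.condensate_quant import LabelMask, count_subclusters

        sim = syn.render_demixed_condensates(
            {2: 1.0}, spot_sd_um=0.15, separation_um=0.5, params=self._params()
        )
        mask = LabelMask(sim.label_mask, 0.1, {})
        res = count_subclusters(
            sim.stack.frame(0, 1),
            mask,
            smoothing_sd_px=0.5,
            prominence_fraction=0.3,
            min_separation_um=0.4,
        )
        assert (res.counts["k"] == 2).all()
        assert res.fraction_multi == 1.0

    def test_unresolvable_separation_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            syn.render_demixed_condensates(
                {1: 1.0}, spot_sd_um=0.3, separation_um=0.5, params=self._params()
            )
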