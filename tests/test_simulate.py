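"""Generator correctness: determinism, degenerate limits, closed forms."""

import numpy as np
import pytest

from woundlab import simulate as sim
from woundlab import tracks as trk


class TestTrackGenerator:
    def test_full_bias_no_noise_is_straight_line(self):
        cells = sim.gen_tracks(sim.TrackSimParams(
            n_cells=3, bias_strength=1.0, angular_noise_sd=0.0,
            bias_direction_deg=30.0, seed=0))
        for c in cells:
            m = trk.compute_metrics(c)
            assert m.straightness == pytest.approx(1.0)
            assert m.orientation == pytest.approx(1.0)

    def test_unbiased_walk_mean_orientation_near_zero(self):
        # Monte-Carlo: uniform initial headings make displacement
        # directions isotropic, so mean orientation ≈ 0
        cells = sim.gen_tracks(sim.TrackSimParams(
            n_cells=1000, n_steps=15, bias_strength=0.0,
            angular_noise_sd=60.0, seed=5))
        o = trk.metrics_table(cells)["orientation"].to_numpy()
        assert abs(np.nanmean(o)) < 3.0 / np.sqrt(len(o))  # ~3 SE of mean

    def test_same_seed_identical(self):
        p = sim.TrackSimParams(seed=7)
        a = sim.gen_tracks(p)
        b = sim.gen_tracks(p)
        assert all(np.array_equal(x.x, y.x) and np.array_equal(x.y, y.y)
                   for x, y in zip(a, b))

    def test_step_length_constant(self):
        (cell,) = sim.gen_tracks(sim.TrackSimParams(n_cells=1, mean_step=5.0,
                                                    seed=1))
        steps = np.hypot(np.diff(cell.x), np.diff(cell.y))
        assert np.allclose(steps, 5.0)


class TestWoundGenerator:
    @pytest.mark.parametrize("closure, factor", [(1.0, 0.0), (0.0, 1.0),
                                                 (0.5, 0.5)])
    def test_closure_scales_area(self, closure, factor):
        ti, tf = sim.gen_wound_masks(90.0, closure, pixel_size=0.5)
        assert tf.sum() == pytest.approx(ti.sum() * factor, abs=ti.shape[0])

    def test_band_too_wide_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_wound_masks(600.0, 0.5, fov=(64, 64), pixel_size=1.0)

    def test_band_width_as_specified(self):
        ti, _ = sim.gen_wound_masks(90.0, 0.0, pixel_size=0.5)
        widths = ti.sum(axis=1)
        assert np.all(widths == 180)


class TestEdgeGenerator:
    def test_no_waves_means_flat_cell_interior(self):
        p = sim.EdgeSimParams(frames=10, fov=(80, 60), wave_frequency=0.0,
                              noise_sd=0.0, seed=0)
        stack, masks, _ = sim.gen_edge_stack(p)
        interior = stack[:, p.edge_row + 5:, :]
        assert np.allclose(interior, p.cell_level)

    def test_scripted_protrusion_speed_by_construction(self):
        s = sim.FilopodiumScript(2, 30, 4.0, 5, 2, 5, "exploratory")
        p = sim.EdgeSimParams(frames=20, fov=(80, 60), filopodia_script=[s],
                              wave_frequency=0.0, seed=0)
        _, _, gt = sim.gen_edge_stack(p)
        ev = gt["filopodia"][0]
        assert ev["protrusion_speed"] == pytest.approx(4.0 / (5 * p.dt))

    def test_same_seed_identical_stack(self):
        p = sim.EdgeSimParams(frames=5, fov=(60, 40), seed=9)
        a, _, _ = sim.gen_edge_stack(p)
        b, _, _ = sim.gen_edge_stack(p)
        assert np.array_equal(a, b)

    def test_filopodium_outside_field_rejected(self):
        s = sim.FilopodiumScript(0, 500, 3.0, 4, 1, 4)
        with pytest.raises(ValueError):
            sim.EdgeSimParams(fov=(80, 60), filopodia_script=[s])


class TestFrapGenerator:
    def test_plateau_closed_form(self):
        p = sim.FrapSimParams(mobile_fraction=0.6, k=0.5, noise_sd=0.0)
        trace, _ = sim.gen_frap_trace(p)
        plateau = p.F0 + 0.6 * (p.F_pre - p.F0)
        assert trace.F_raw[-1] == pytest.approx(plateau, rel=1e-4)

    def test_immobile_pool_flat_trace(self):
        trace, _ = sim.gen_frap_trace(sim.FrapSimParams(mobile_fraction=0.0,
                                                        noise_sd=0.0))
        assert np.allclose(trace.F_raw, trace.F_raw[0])

    def test_fully_mobile_recovers_to_prebleach(self):
        p = sim.FrapSimParams(mobile_fraction=1.0, k=1.0, post_frames=200,
                              noise_sd=0.0)
        trace, _ = sim.gen_frap_trace(p)
        assert trace.F_raw[-1] == pytest.approx(p.F_pre, rel=1e-4)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sim.FrapSimParams(F0=2000.0)  # F0 > F_pre
        with pytest.raises(ValueError):
            sim.FrapSimParams(k=0.0)


class TestFretGenerator:
    def test_equal_ratios_give_unity(self):
        *_, gt = sim.gen_fret_pair(sim.FretSimParams(ratio_front=1.1,
                                                     ratio_rear=1.1))
        assert gt["front_rear_ratio"] == 1.0

    def test_noiseless_pixelwise_ratio_exact(self):
        p = sim.FretSimParams(background=0.0, noise_sd=0.0,
                              ratio_front=1.3, ratio_rear=0.9)
        fret, cfp, _, gt = sim.gen_fret_pair(p)
        cell = gt["cell_mask"]
        ratio = fret[cell] / cfp[cell]
        assert set(np.round(ratio, 9)) <= {0.9, 1.3}

    def test_same_seed_identical(self):
        p = sim.FretSimParams(noise_sd=10.0, seed=3)
        a = sim.gen_fret_pair(p)[0]
        b = sim.gen_fret_pair(p)[0]
        assert np.array_equal(a, b)


class TestMtocGenerator:
    @pytest.mark.parametrize("p_pol, expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_degenerate_fractions(self, p_pol, expected):
        pop = sim.gen_mtoc_population(sim.MtocSimParams(
            n_cells=50, p_polarized=p_pol, seed=0))
        assert np.mean([pol for *_, pol in pop]) == expected

    def test_recovered_fraction_within_binomial_noise(self):
        n, p = 400, 0.8
        pop = sim.gen_mtoc_population(sim.MtocSimParams(
            n_cells=n, p_polarized=p, seed=21))
        frac = np.mean([pol for *_, pol in pop])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)
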