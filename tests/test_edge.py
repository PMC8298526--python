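"""Superposition maps, filopodium detection/kinetics/classing, shape metrics."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from woundlab import edge as edg
from woundlab import simulate as sim
from woundlab.io import Calibration


def make_series(masks, pixel_size=0.2, dt=3.7, **kw):
    return edg.LeadingEdgeSeries(
        masks=np.asarray(masks), calibration=Calibration(pixel_size, dt), **kw)


class TestSuperpose:
    def test_static_cell_zero_metric(self):
        m = np.zeros((60, 80), bool)
        m[30:, :] = True
        series = make_series([m, m, m])
        res = edg.superpose(series, 0.0, 2 * 3.7)
        assert not res.advance_mask.any()
        assert not res.retraction_mask.any()
        assert res.accumulated_protrusion_per_perimeter == 0.0

    def test_uniform_advance_area_over_length_identity(self):
        # a straight 50 μm edge advancing 1 μm covers 50 μm² → metric 1 μm
        px = 0.2
        w = int(50 / px)
        m0 = np.zeros((100, w), bool)
        m0[50:, :] = True
        m1 = m0.copy()
        m1[45:, :] = True  # 5 px = 1 μm advance
        series = make_series([m0, m1], pixel_size=px, perimeter_front=50.0)
        res = edg.superpose(series, 0.0, 3.7)
        assert res.accumulated_protrusion_per_perimeter == pytest.approx(1.0)

    def test_masks_pairwise_disjoint_and_partition(self):
        rng = np.random.default_rng(0)
        m0 = rng.random((40, 40)) > 0.5
        m1 = rng.random((40, 40)) > 0.5
        series = make_series([m0, m1])
        res = edg.superpose(series, 0.0, 3.7)
        assert not (res.advance_mask & res.retraction_mask).any()
        assert not (res.advance_mask & res.still_mask).any()
        assert not (res.retraction_mask & res.still_mask).any()
        assert np.array_equal(
            res.advance_mask | res.retraction_mask | res.still_mask, m0 | m1)

    def test_window_outside_series_errors(self):
        m = np.zeros((20, 20), bool)
        m[10:] = True
        with pytest.raises(ValueError):
            edg.superpose(make_series([m, m]), 0.0, 100.0)


@pytest.fixture(scope="module")
def scripted_scene():
    script = [
        sim.FilopodiumScript(5, 40, 4.0, 8, 4, 10, "exploratory"),
        sim.FilopodiumScript(8, 120, 3.0, 6, 3, 8, "lamellipodic"),
        sim.FilopodiumScript(12, 220, 5.0, 10, 5, 12, "exploratory"),
    ]
    p = sim.EdgeSimParams(frames=50, filopodia_script=script,
                          wave_frequency=0.0, wave_speed=0.0, seed=3)
    stack, masks, gt = sim.gen_edge_stack(p)
    series = edg.LeadingEdgeSeries(
        masks=masks, calibration=Calibration(p.pixel_size, p.dt))
    events, per_frame = edg.detect_filopodia(series)
    return p, gt, events, per_frame


class TestDetectFilopodia:
    def test_smooth_edge_no_events(self):
        m = np.zeros((60, 80), bool)
        m[30:, :] = True
        events, per_frame = edg.detect_filopodia(make_series([m] * 6))
        assert events == []
        assert (per_frame["n_filopodia"] == 0).all()

    def test_all_scripted_events_found(self, scripted_scene):
        p, gt, events, _ = scripted_scene
        assert len(events) == len(gt["filopodia"])

    def test_max_length_within_half_micron(self, scripted_scene):
        p, gt, events, _ = scripted_scene
        got = sorted(e.max_length for e in events)
        want = sorted(g["max_length"] for g in gt["filopodia"])
        assert np.allclose(got, want, atol=0.5)

    def test_count_per_um_matches_script(self, scripted_scene):
        p, gt, events, per_frame = scripted_scene
        # a frame where all three scripted filopodia are near max length
        frame = 20
        row = per_frame.loc[per_frame["frame"] == frame].iloc[0]
        assert row["n_filopodia"] == 3
        assert row["count_per_um"] == pytest.approx(3 / gt["front_length_um"])

    def test_speeds_within_ten_percent(self, scripted_scene):
        p, gt, events, _ = scripted_scene
        by_base = {round(e.base_col / 10) * 10: e for e in events}
        for g in gt["filopodia"]:
            ev = by_base[g["base_col"]]
            assert ev.protrusion_speed == pytest.approx(
                g["protrusion_speed"], rel=0.10)
            assert ev.overall_speed == pytest.approx(
                g["overall_speed"], rel=0.10)

    def test_class_labels_recovered(self, scripted_scene):
        p, gt, events, _ = scripted_scene
        by_base = {round(e.base_col / 10) * 10: e for e in events}
        for g in gt["filopodia"]:
            assert by_base[g["base_col"]].class_label == g["class_label"]


class TestFilopodiumSpeeds:
    def test_dwell_discounted_from_protrusion_speed(self):
        # 4 μm reached at 20 s, retracted by 40 s
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        lengths = np.array([0.0, 2.0, 4.0, 2.0, 0.0])
        overall, prot = edg.filopodium_speeds(lengths, t)
        assert (overall, prot) == (pytest.approx(0.1), pytest.approx(0.2))

    def test_no_dwell_protrusion_twice_overall(self):
        t = np.linspace(0.0, 30.0, 7)
        lengths = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        overall, prot = edg.filopodium_speeds(lengths, t)
        assert prot == pytest.approx(2.0 * overall)

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            edg.filopodium_speeds(np.array([3.0, 1.0]), np.array([0.0, 5.0]))


class TestShapeDescriptors:
    def test_disk_circularity_near_one(self):
        m = np.zeros((300, 300), bool)
        rr, cc = disk((150, 150), 100)
        m[rr, cc] = True
        area, perim, circ, roundn = edg.shape_descriptors(m, 1.0)
        assert circ == pytest.approx(1.0, abs=0.05)
        assert roundn == pytest.approx(1.0, abs=0.05)
        assert area == pytest.approx(np.pi * 100**2, rel=0.01)

    def test_two_to_one_ellipse_roundness_half(self):
        m = np.zeros((300, 500), bool)
        rr, cc = ellipse(150, 250, 80, 160)
        m[rr, cc] = True
        *_, roundn = edg.shape_descriptors(m, 1.0)
        assert roundn == pytest.approx(0.5, abs=0.03)

    def test_square_circularity_pi_over_four(self):
        m = np.zeros((200, 200), bool)
        m[50:150, 50:150] = True
        *_, circ, _ = edg.shape_descriptors(m, 1.0)
        assert circ == pytest.approx(np.pi / 4, abs=0.05)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            edg.shape_descriptors(np.zeros((10, 10), bool), 1.0)
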