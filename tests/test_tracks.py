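"""Track polarity metrics: definitional examples, identities, equivariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woundlab import tracks as trk
from woundlab.simulate import TrackSimParams, gen_tracks

from conftest import make_track


class TestPathAndDisplacement:
    @pytest.mark.parametrize(
        "points, expected_T, expected_D",
        [
            ([(0, 0), (3, 0), (3, 4)], 7.0, 5.0),
            ([(0, 0), (3, 4)], 5.0, 5.0),
            ([(0, 0), (0, 0), (0, 0)], 0.0, 0.0),
            ([(0, 0), (1, 0), (0, 0)], 2.0, 0.0),  # closed loop
        ],
    )
    def test_lengths(self, points, expected_T, expected_D):
        track = make_track(points)
        assert trk.path_length(track) == pytest.approx(expected_T)
        assert trk.displacement_vector(track)[0] == pytest.approx(expected_D)

    def test_displacement_angles(self):
        assert trk.displacement_vector(make_track([(0, 0), (-1, 0)]))[1] == 180.0
        mag, ang = trk.displacement_vector(make_track([(0, 0), (1, 0), (0, 0)]))
        assert mag == 0.0 and math.isnan(ang)  # loop: angle undefined

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            make_track([(0, 0)])


class TestMetricDefinitions:
    def test_straightness_examples(self):
        assert trk.straightness(make_track([(0, 0), (5, 0)])) == 1.0
        assert trk.straightness(
            make_track([(0, 0), (3, 0), (3, 4)])
        ) == pytest.approx(5.0 / 7.0)
        assert trk.straightness(make_track([(0, 0), (1, 0), (0, 0)])) == 0.0
        assert math.isnan(trk.straightness(make_track([(0, 0), (0, 0)])))

    @pytest.mark.parametrize(
        "direction_deg, expected_O",
        [(0.0, 1.0), (90.0, 0.0), (60.0, 0.5), (180.0, -1.0)],
    )
    def test_orientation_cosine(self, direction_deg, expected_O):
        th = math.radians(direction_deg)
        track = make_track([(0, 0), (math.cos(th), math.sin(th))], wound_deg=0.0)
        assert trk.orientation(track) == pytest.approx(expected_O, abs=1e-12)

    def test_polarity_index_is_product(self):
        assert trk.polarity_index(1.0, 1.0) == 1.0
        assert trk.polarity_index(0.7, 0.0) == 0.0
        assert trk.polarity_index(0.5, -1.0) == -0.5

    def test_speeds_hand_oracle(self):
        # T=7, D=5 over 1 h, wound direction along the displacement:
        # O = 1, S = 5/7, polarized speed = 5·(5/7)
        track = make_track([(0, 0), (3, 0), (3, 4)], dt=0.5,
                           wound_deg=math.degrees(math.atan2(4, 3)))
        sT, sD, sP = trk.speeds(track)
        assert (sT, sD) == (pytest.approx(7.0), pytest.approx(5.0))
        assert sP == pytest.approx(5.0 * 5.0 / 7.0)

    def test_stationary_cell_speeds_zero(self):
        assert trk.speeds(make_track([(1, 1), (1, 1), (1, 1)])) == (0, 0, 0)

    def test_retracting_cell_polarized_speed_negative(self):
        track = make_track([(0, 0), (-5, 0)], wound_deg=0.0)
        sT, sD, sP = trk.speeds(track)
        assert sP == pytest.approx(-sD)


class TestGroupSummary:
    def test_identical_tracks_sem_zero(self):
        tracks = [make_track([(0, 0), (3, 4)], cell_id=f"c{i}") for i in range(4)]
        tab = trk.summarize_group(tracks)
        assert (tab["sem"] == 0).all()
        assert (tab["n"] == 4).all()

    def test_mean_of_two_polarities(self):
        best = make_track([(0, 0), (5, 0)], wound_deg=0.0)       # P = 1
        sideways = make_track([(0, 0), (0, 5)], wound_deg=0.0)   # P = 0
        tab = trk.summarize_group([best, sideways]).set_index("metric")
        assert tab.loc["polarity_index", "mean"] == pytest.approx(0.5)

    def test_undefined_orientation_excluded_and_counted(self):
        loop = make_track([(0, 0), (1, 0), (0, 0)])
        mover = make_track([(0, 0), (5, 0)])
        tab = trk.summarize_group([loop, mover]).set_index("metric")
        assert tab.loc["orientation", "n"] == 1
        assert tab.loc["orientation", "n_excluded"] == 1

    def test_fully_biased_walk_perfectly_oriented(self):
        cells = gen_tracks(TrackSimParams(
            n_cells=5, bias_strength=1.0, angular_noise_sd=0.0, seed=3))
        tab = trk.summarize_group(cells).set_index("metric")
        assert tab.loc["orientation", "mean"] == pytest.approx(1.0)
        assert tab.loc["orientation", "sem"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["straightness", "mean"] == pytest.approx(1.0)


@st.composite
def random_walks(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    coords = draw(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=n, max_size=n,
        )
    )
    wound = draw(st.floats(0, 359.9))
    return make_track(coords, wound_deg=wound)


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(random_walks())
    def test_identities(self, track):
        """D <= T, S = D/T, P = S·O, polarized = speed_D·P on random tracks."""
        m = trk.compute_metrics(track)
        assert m.displacement <= m.trajectory_len + 1e-9
        if m.trajectory_len > 0:
            assert m.straightness == pytest.approx(
                min(m.displacement / m.trajectory_len, 1.0), abs=1e-9)
        if not math.isnan(m.polarity_index):
            assert m.polarity_index == pytest.approx(
                m.straightness * m.orientation, abs=1e-9)
            assert m.polarized_speed == pytest.approx(
                m.speed_D * m.polarity_index, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(random_walks(), st.floats(1.0, 359.0))
    def test_rotation_equivariance(self, track, rot_deg):
        """Rotating points and wound direction together changes nothing."""
        th = math.radians(rot_deg)
        c, s = math.cos(th), math.sin(th)
        rotated = trk.TrackedCell(
            cell_id=track.cell_id,
            t=track.t,
            x=c * track.x - s * track.y,
            y=s * track.x + c * track.y,
            wound_direction_deg=track.wound_direction_deg + rot_deg,
        )
        m0 = trk.compute_metrics(track)
        m1 = trk.compute_metrics(rotated)
        for f in ("trajectory_len", "displacement", "straightness",
                  "orientation", "polarity_index", "polarized_speed"):
            v0, v1 = getattr(m0, f), getattr(m1, f)
            if math.isnan(v0):
                assert math.isnan(v1)
            else:
                assert v1 == pytest.approx(v0, abs=1e-7)

    def test_orientation_monotone_in_bias(self):
        """Mean orientation does not decrease as the directional bias grows."""
        means = []
        for b in (0.0, 0.3, 0.6, 1.0):
            cells = gen_tracks(TrackSimParams(
                n_cells=60, n_steps=20, bias_strength=b,
                angular_noise_sd=40.0, seed=42))
            tab = trk.metrics_table(cells)
            means.append(np.nanmean(tab["orientation"]))
        assert all(b >= a - 0.05 for a, b in zip(means, means[1:]))
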