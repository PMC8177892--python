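"""Bead-position equations, MSD estimators, zones and retention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wntbead import bead_dynamics as bd
from tests.conftest import build_track

finite = st.floats(-1e3, 1e3, allow_nan=False)


class TestDistance:
    @pytest.mark.parametrize("p,q,expected", [
        ((0, 0), (3, 4), 5.0),
        ((2, -1), (2, -1), 0.0),
        ((1, 1), (4, 5), 5.0),
    ])
    def test_euclidean(self, p, q, expected):
        assert bd.distance(p, q) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bd.distance((0, np.nan), (1, 1))


class TestRadiusRatio:
    def test_collinear_halfway(self, track_factory):
        tr = track_factory(
            bead_path=np.tile([3.0, 4.0], (10, 1)),
            membrane_path=np.tile([6.0, 8.0], (10, 1)),
        )
        assert bd.radius_ratio(tr, 0) == pytest.approx(0.5)

    def test_bead_at_membrane_point(self, track_factory):
        tr = track_factory(
            bead_path=np.tile([6.0, 8.0], (10, 1)),
            membrane_path=np.tile([6.0, 8.0], (10, 1)),
        )
        assert bd.radius_ratio(tr, 0) == pytest.approx(1.0)

    def test_membrane_need_not_be_collinear(self, track_factory):
        # centre (0,0), bead (1,0), membrane (0,2): ratio uses distances only
        tr = track_factory(
            bead_path=np.tile([1.0, 0.0], (10, 1)),
            membrane_path=np.tile([0.0, 2.0], (10, 1)),
        )
        assert bd.radius_ratio(tr, 0) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(dx=finite, dy=finite,
           angle=st.floats(0, 2 * np.pi, allow_nan=False),
           scale=st.floats(0.01, 100, allow_nan=False))
    def test_similarity_invariance(self, dx, dy, angle, scale):
        """The ratio is unchanged by translating, rotating and uniformly
        scaling all three tracked points together."""
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        shift = np.array([dx, dy])

        def transform(points):
            return (scale * points @ rot.T) + shift

        base = build_track(
            n_minutes=3,
            bead_path=np.tile([2.0, 1.0], (3, 1)),
            membrane_path=np.tile([4.0, 3.0], (3, 1)),
        )
        moved = build_track(
            n_minutes=3,
            cell_path=transform(base.p_cell),
            bead_path=transform(base.p_bead),
            membrane_path=transform(base.p_membrane),
        )
        assert bd.radius_ratio(moved, 0) == pytest.approx(
            bd.radius_ratio(base, 0), rel=1e-9)

    def test_degenerate_membrane_errors(self, track_factory):
        tr = track_factory()
        tr.p_membrane[0] = tr.p_cell[0]  # zero radius at t=0
        with pytest.raises(bd.DegenerateGeometryError):
            bd.radius_ratio(tr, 0)


class TestPositionSeries:
    def test_constant_geometry_constant_series(self, track_factory):
        series = bd.position_series(track_factory())
        assert np.allclose(series.radius_ratio, 0.5)
        assert np.allclose(series.np_bead, [5.0, 0.0])

    def test_reindexed_to_uptake(self, track_factory):
        contact = np.zeros(50, dtype=bool)
        contact[37:] = True
        series = bd.position_series(track_factory(n_minutes=50,
                                                  in_contact=contact))
        assert series.minutes[0] == 0
        assert series.t_original[0] == 37

    def test_no_contact_errors(self, track_factory):
        tr = track_factory(in_contact=np.zeros(10, dtype=bool))
        with pytest.raises(bd.InsufficientDataError):
            bd.position_series(tr)


class TestWindowMeans:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return bd.BeadPositionSeries(
            cell_id="c0",
            minutes=np.arange(len(values)),
            t_original=np.arange(len(values)),
            radius_ratio=values,
            np_bead=np.zeros((len(values), 2)),
        )

    def test_constant_series(self):
        wms = bd.window_means(self._series(np.full(181, 0.5)))
        assert [wm.mean for wm in wms] == [0.5, 0.5, 0.5]
        assert not any(wm.partial for wm in wms)

    def test_linear_ramp_first_window(self):
        # ratio(t) = t/180: first-window mean = (0+...+30)/31/180 = 15/180
        wms = bd.window_means(self._series(np.arange(181) / 180.0))
        assert wms[0].mean == pytest.approx(15.0 / 180.0)
        assert wms[1].mean == pytest.approx(np.mean(np.arange(31, 121)) / 180)

    def test_partial_and_absent_windows(self):
        wms = bd.window_means(self._series(np.full(101, 0.4)))
        assert wms[1].partial and wms[1].mean == pytest.approx(0.4)
        assert wms[2].mean is None and wms[2].n_minutes == 0


class TestMsd:
    def test_stationary_cell_zero(self, track_factory):
        assert bd.msd_cell(track_factory()) == 0.0

    def test_constant_velocity(self, track_factory):
        path = np.column_stack([2.0 * np.arange(10), np.zeros(10)])
        assert bd.msd_cell(track_factory(cell_path=path)) == pytest.approx(4.0)

    def test_estimator_equals_hand_mean_on_toy_track(self, track_factory):
        # 5-point track: MSD_bead must equal the by-hand mean of squared
        # NP_bead differences
        cell = np.array([[0, 0], [1, 0], [1, 1], [2, 1], [2, 2]], float)
        bead = np.array([[1, 0], [3, 0], [2, 2], [4, 1], [2, 3]], float)
        tr = track_factory(n_minutes=5, cell_path=cell, bead_path=bead)
        np_bead = bead - cell
        expected = np.mean(np.sum(np.diff(np_bead, axis=0) ** 2, axis=1))
        assert bd.msd_bead(tr) == pytest.approx(expected)

    def test_bead_comoving_with_cell_zero(self, track_factory):
        rng = np.random.default_rng(0)
        cell = np.cumsum(rng.normal(size=(20, 2)), axis=0)
        tr = track_factory(n_minutes=20, cell_path=cell,
                           bead_path=cell + [3.0, 0.0])
        assert bd.msd_bead(tr) == pytest.approx(0.0)

    def test_static_cell_moving_bead(self, track_factory):
        bead = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        tr = track_factory(bead_path=bead)
        assert bd.msd_bead(tr) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25)
    @given(dx=finite, dy=finite)
    def test_msd_bead_rigid_translation_invariant(self, dx, dy):
        rng = np.random.default_rng(1)
        cell = np.cumsum(rng.normal(size=(15, 2)), axis=0)
        bead = cell + rng.normal(size=(15, 2))
        shift = np.array([dx, dy])
        a = build_track(n_minutes=15, cell_path=cell, bead_path=bead)
        b = build_track(n_minutes=15, cell_path=cell + shift,
                        bead_path=bead + shift)
        assert bd.msd_bead(a) == pytest.approx(bd.msd_bead(b), abs=1e-6)

    def test_too_short_track_errors(self, track_factory):
        with pytest.raises(bd.InsufficientDataError):
            bd.msd_cell(track_factory(n_minutes=1))


class TestZones:
    @pytest.mark.parametrize("ratio,zone", [
        (0.85, "periphery"), (0.5, "intermediate"), (0.2, "centre"),
        (0.7, "intermediate"), (0.3, "centre"), (1.0, "periphery"),
    ])
    def test_band_assignment(self, ratio, zone):
        assert bd.assign_zone(ratio).zone == zone

    def test_beyond_membrane_flagged_not_clamped(self):
        call = bd.assign_zone(1.2)
        assert call.zone == "periphery" and call.out_of_cell

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            bd.assign_zone(-0.1)


class TestRetention:
    def _track_with_loss(self, d, divided_at=None):
        n = 301
        contact = np.zeros(n, dtype=bool)
        contact[:d] = True
        return build_track(n_minutes=n, in_contact=contact,
                           divided_at=divided_at)

    def test_loss_within_window_drops(self):
        rec = bd.classify_retention(self._track_with_loss(100))
        assert rec.outcome == "drops" and rec.t_loss == 100

    def test_contact_beyond_window_retains(self):
        rec = bd.classify_retention(self._track_with_loss(201))
        assert rec.outcome == "retains"

    def test_division_within_window_excluded(self):
        rec = bd.classify_retention(self._track_with_loss(250, divided_at=90))
        assert rec.outcome == "excluded"

    def test_boundary_scan_switches_at_window_length(self):
        """Scanning contact duration 1..300 min, the call flips from
        'drops' to 'retains' exactly between 180 and 181 min."""
        outcomes = [bd.classify_retention(self._track_with_loss(d)).outcome
                    for d in range(1, 301)]
        assert outcomes[179] == "drops"       # d = 180
        assert outcomes[180] == "retains"     # d = 181
        assert set(outcomes[:180]) == {"drops"}
        assert set(outcomes[180:]) == {"retains"}

    def test_no_uptake_errors(self, track_factory):
        tr = track_factory(in_contact=np.zeros(10, dtype=bool))
        with pytest.raises(ValueError):
            bd.classify_retention(tr)
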