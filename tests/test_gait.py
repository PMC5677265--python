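"""Gait events, membership functions, decomposition, cycle landmarks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitproxy as gp
from gaitproxy import GaitEvents
from gaitproxy.errors import (DegenerateShapeError, DomainError,
                              ParameterError, StructuralError,
                              UnsupportedGaitError)


def simple_events():
    """Left stance [0,10), right stance [6,20): one double support [6,10)."""
    return GaitEvents(ic_left=[0], fc_left=[10], ic_right=[6], fc_right=[20])


class TestDetectGaitEvents:
    def test_threshold_crossing_example(self):
        grf_l = np.array([0, 5, 12, 300, 280, 8, 0], dtype=float)
        grf_r = np.zeros(7)
        ev = gp.detect_gait_events(grf_l, grf_r, threshold=10,
                                   min_run_duration=0.0)
        assert list(ev.ic_left) == [2]
        assert list(ev.fc_left) == [5]

    def test_constant_zero_has_no_events(self):
        ev = gp.detect_gait_events(np.zeros(50), np.zeros(50))
        assert len(ev.ic_left) == 0 and len(ev.ic_right) == 0

    def test_two_stance_runs_give_ordered_pairs(self):
        grf = np.zeros(100)
        grf[10:40] = 500.0
        grf[60:95] = 450.0
        ev = gp.detect_gait_events(grf, np.zeros(100), min_run_duration=0.0)
        assert list(ev.ic_left) == [10, 60]
        assert list(ev.fc_left) == [40, 95]

    def test_short_runs_debounced(self):
        grf = np.zeros(200)
        grf[50:100] = 400.0
        grf[102] = 30.0          # chatter blip in swing
        grf[70] = 0.0            # chatter dropout in stance
        ev = gp.detect_gait_events(grf, np.zeros(200), sampling_rate=128.0,
                                   min_run_duration=0.1)
        assert list(ev.ic_left) == [50]
        assert list(ev.fc_left) == [103]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            gp.detect_gait_events(np.zeros(10), np.zeros(10), threshold=-1)

    def test_idempotence_on_thresholded_signal(self):
        grf_l, grf_r, _ = gp.generate_vgrf_profiles(gp.GaitTemplateParams(),
                                                    6, seed=4)
        ev1 = gp.detect_gait_events(grf_l, grf_r)
        # rebuild a binary force from the events; detection must reproduce them
        rebuilt_l = np.where(ev1.stance_mask("left", len(grf_l)), 100.0, 0.0)
        rebuilt_r = np.where(ev1.stance_mask("right", len(grf_r)), 100.0, 0.0)
        ev2 = gp.detect_gait_events(rebuilt_l, rebuilt_r)
        np.testing.assert_array_equal(ev1.ic_left, ev2.ic_left)
        np.testing.assert_array_equal(ev1.fc_right, ev2.fc_right)


class TestExactMembership:
    def test_force_ratio(self):
        m = gp.exact_membership([600.0], [200.0])
        assert m.w_left[0] == pytest.approx(0.75)
        assert m.w_right[0] == pytest.approx(0.25)

    def test_equal_forces_split_evenly(self):
        m = gp.exact_membership([350.0], [350.0])
        assert m.w_left[0] == m.w_right[0] == pytest.approx(0.5)

    def test_single_support_limit(self):
        m = gp.exact_membership([500.0], [0.0])
        assert m.w_left[0] == 1.0

    def test_negative_force_rejected(self):
        with pytest.raises(DomainError):
            gp.exact_membership([-1.0], [1.0])

    def test_undefined_samples_carry_last_value(self):
        m = gp.exact_membership([0, 600, 0, 0], [0, 200, 0, 0])
        assert m.w_left[0] == 0.5          # before any defined value
        assert m.w_left[2] == m.w_left[3] == pytest.approx(0.75)


class TestEventMembership:
    def test_double_support_ramp_values(self):
        # right IC at 6, left FC at 10: ramp 1, .75, .5, .25 then 0 in swing
        m = gp.event_membership(simple_events(), 20)
        np.testing.assert_allclose(m.w_left[6:11], [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_single_support_is_one(self):
        m = gp.event_membership(simple_events(), 20)
        np.testing.assert_array_equal(m.w_left[0:6], 1.0)   # left single support
        np.testing.assert_array_equal(m.w_left[10:20], 0.0)  # left swing

    def test_pair_sums_to_one_everywhere(self):
        m = gp.event_membership(simple_events(), 20)
        np.testing.assert_allclose(m.w_left + m.w_right, 1.0)

    def test_interior_flight_rejected(self):
        ev = GaitEvents(ic_left=[0, 30], fc_left=[10, 40],
                        ic_right=[15], fc_right=[25])
        with pytest.raises(UnsupportedGaitError):
            gp.event_membership(ev, 45)

    def test_agrees_with_exact_outside_double_support(self):
        grf_l, grf_r, ev = gp.generate_vgrf_profiles(gp.GaitTemplateParams(),
                                                     8, seed=6)
        approx = gp.event_membership(ev, len(grf_l))
        exact = gp.exact_membership(grf_l, grf_r)
        masks = gp.phase_masks(ev, len(grf_l))
        outside_ds = masks["single_left"] | masks["single_right"]
        np.testing.assert_allclose(approx.w_left[outside_ds],
                                   exact.w_left[outside_ds])
        assert not np.allclose(approx.w_left[masks["double"]],
                               exact.w_left[masks["double"]])


class TestDecomposition:
    def test_identity_membership(self):
        rec = gp.TimeSeriesRecording(128.0, ax=[1.0, 2.0], ay=[0.0, 1.0],
                                     az=[9.8, 9.8])
        m = gp.MembershipPair(w_left=np.ones(2), w_right=np.zeros(2))
        d = gp.decompose_acceleration(rec, m)
        np.testing.assert_array_equal(d["ax_left"], rec.ax)
        np.testing.assert_array_equal(d["ax_right"], 0.0)

    def test_pointwise_arithmetic(self):
        rec = gp.TimeSeriesRecording(128.0, ax=[2.0, -4.0], ay=[0.0, 0.0],
                                     az=[0.0, 0.0])
        m = gp.MembershipPair(w_left=[0.25, 0.5], w_right=[0.75, 0.5])
        d = gp.decompose_acceleration(rec, m)
        np.testing.assert_allclose(d["ax_left"], [0.5, -2.0])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=40),
           st.integers(0, 2 ** 31 - 1))
    def test_conservation_property(self, ax, seed):
        n = len(ax)
        w = np.random.default_rng(seed).uniform(0, 1, n)
        rec = gp.TimeSeriesRecording(128.0, ax=ax, ay=np.zeros(n),
                                     az=np.zeros(n))
        d = gp.decompose_acceleration(
            rec, gp.MembershipPair(w_left=w, w_right=1 - w))
        np.testing.assert_allclose(d["ax_left"] + d["ax_right"], rec.ax,
                                   rtol=0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        rec = gp.TimeSeriesRecording(128.0, ax=[1.0, 2.0], ay=[0.0, 0.0],
                                     az=[0.0, 0.0])
        with pytest.raises(StructuralError):
            gp.decompose_acceleration(
                rec, gp.MembershipPair(w_left=np.ones(3), w_right=np.zeros(3)))


class TestCyclesAndLandmarks:
    def test_cycles_are_consecutive_ic_ranges(self):
        ev = GaitEvents(ic_left=[100, 240, 386], fc_left=[180, 320, 460],
                        ic_right=[170, 310], fc_right=[250, 390])
        assert gp.segment_cycles(ev, "left") == [(100, 240), (240, 386)]
        assert len(gp.segment_cycles(ev, "right")) == 1

    def test_fewer_than_two_ics_gives_empty_list(self):
        ev = GaitEvents(ic_left=[5], fc_left=[20], ic_right=[], fc_right=[])
        assert gp.segment_cycles(ev, "left") == []

    def test_jitter_free_cycles_equal_length(self):
        # cycle duration commensurate with the sampling grid (1.0 s @ 128 Hz)
        params = gp.GaitTemplateParams(cycle_duration=1.0)
        _, _, ev = gp.generate_vgrf_profiles(params, 6, seed=0)
        lengths = {b - a for a, b in gp.segment_cycles(ev, "left")}
        assert len(lengths) == 1

    def test_tabulated_nine_point_example(self):
        cycle = [0, 400, 700, 650, 500, 620, 690, 300, 0]
        cp = gp.extract_critical_points(cycle)
        assert (cp.vp1_value, cp.vp1_index) == (700.0, 2)
        assert (cp.tr_value, cp.tr_index) == (500.0, 4)
        assert (cp.vp2_value, cp.vp2_index) == (690.0, 6)

    def test_symmetric_curve_has_equal_peaks(self):
        s = np.linspace(0, 1, 101)
        m_curve = np.sin(np.pi * s) * (1 - 0.4 * np.sin(np.pi * s) ** 4)
        cp = gp.extract_critical_points(m_curve)
        assert cp.vp1_value == pytest.approx(cp.vp2_value)

    def test_degenerate_shape_carries_single_extremum(self):
        single_bump = [0, 2, 5, 9, 5, 2, 0]
        with pytest.raises(DegenerateShapeError) as exc:
            gp.extract_critical_points(single_bump)
        assert exc.value.extremum == (9.0, 3)


class TestPhaseMasks:
    def test_double_support_is_stance_intersection(self):
        ev = simple_events()
        masks = gp.phase_masks(ev, 20)
        both = ev.stance_mask("left", 20) & ev.stance_mask("right", 20)
        np.testing.assert_array_equal(masks["double"], both)
        assert masks["double"].sum() == 4

    def test_support_masks_partition_stance(self):
        _, _, ev = gp.generate_vgrf_profiles(gp.GaitTemplateParams(), 6, seed=2)
        n = int(6 * 1.1 * 128)
        masks = gp.phase_masks(ev, n)
        total_stance = (ev.stance_mask("left", n) | ev.stance_mask("right", n))
        partition = (masks["single_left"].astype(int)
                     + masks["single_right"].astype(int)
                     + masks["double"].astype(int))
        np.testing.assert_array_equal(partition, total_stance.astype(int))

    def test_constructed_overlap_width(self):
        ev = GaitEvents(ic_left=[0], fc_left=[30], ic_right=[18], fc_right=[50])
        masks = gp.phase_masks(ev, 50)
        assert masks["double"].sum() == 12
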