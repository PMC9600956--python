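import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owhto.leg_model import make_leg, mirrored, wbl_fraction
from owhto.planner import (
    AlreadyCorrectedWarning,
    NoSolutionError,
    PlannerConfig,
    PlanningError,
    apply_wedge,
    hinge_point,
    medial_entry,
    plan_osteotomy,
    rotate_distal,
    solve_correction_angle,
    wedge_width,
)


def grid_search_alpha(leg, hinge, target=0.55, step_deg=0.001):
    """Brute-force sweep of the correction angle (vectorized rotation)."""
    alphas = np.arange(0.0, 45.0 + step_deg, step_deg)
    rad = np.radians(alphas)
    a = leg.ankle_center - hinge
    cos, sin = np.cos(rad), np.sin(rad)
    ax = hinge[0] + cos * a[0] - sin * a[1]
    ay = hinge[1] + sin * a[0] + cos * a[1]
    # fraction of plateau width at the joint-line crossing, for each alpha
    M, L, h = leg.plateau_medial, leg.plateau_lateral, leg.hip_center
    D = L - M
    mx, my = ax - h[0], ay - h[1]
    cross_dm = D[0] * my - D[1] * mx
    t = ((h[0] - M[0]) * my - (h[1] - M[1]) * mx) / cross_dm
    return alphas[np.argmin(np.abs(t - target))]


def circle_line_alpha(leg, hinge, target=0.55):
    """Closed-form oracle: intersect the ankle arc about the hinge with the
    hip->target line, take the distal intersection, measure the angle."""
    width = leg.plateau_width
    tgt = leg.plateau_medial + target * (leg.plateau_lateral - leg.plateau_medial)
    h = leg.hip_center
    d = tgt - h
    r = np.linalg.norm(leg.ankle_center - hinge)
    # |h + u d - hinge|^2 = r^2
    e = h - hinge
    A = d @ d
    B = 2 * e @ d
    C = e @ e - r * r
    disc = B * B - 4 * A * C
    assert disc > 0
    u = (-B + math.sqrt(disc)) / (2 * A)  # distal root (u grows downward)
    p = h + u * d
    v1 = leg.ankle_center - hinge
    v2 = p - hinge
    ang = math.atan2(abs(v1[0] * v2[1] - v1[1] * v2[0]), float(v1 @ v2))
    return math.degrees(ang)


class TestConstructionPoints:
    def test_hinge_is_pure_offset_at_zero_depth(self, mean_leg):
        h = hinge_point(mean_leg, 5.0, hinge_depth=0.0)
        assert np.allclose(h, [34.75, 0.0])

    def test_hinge_c_is_10mm_medial_of_hinge_a(self, mean_leg):
        a = hinge_point(mean_leg, 5.0)
        c = hinge_point(mean_leg, 15.0)
        assert np.allclose(c - a, 10.0 * mean_leg.medial_dir)

    def test_default_hinge_lies_distal_to_joint_line(self, mean_leg):
        h = hinge_point(mean_leg, 10.0)
        assert float((h - mean_leg.knee_center) @ mean_leg.distal_dir) > 0

    def test_hinge_offset_outside_plateau_rejected(self, mean_leg):
        with pytest.raises(PlanningError):
            hinge_point(mean_leg, 100.0)
        with pytest.raises(PlanningError):
            hinge_point(mean_leg, 0.0)

    def test_entry_heights(self, mean_leg):
        e30 = medial_entry(mean_leg, 30.0)
        e40 = medial_entry(mean_leg, 40.0)
        assert np.allclose(e30, [-39.75, -30.0])
        assert np.allclose(e40 - e30, 10.0 * mean_leg.distal_dir)

    def test_flare_displaces_entry_medially(self, mean_leg):
        e = medial_entry(mean_leg, 30.0, cortex_flare_deg=10.0)
        shift = float((e - medial_entry(mean_leg, 30.0)) @ mean_leg.medial_dir)
        assert shift == pytest.approx(30.0 * math.tan(math.radians(10.0)), abs=1e-9)
        assert shift == pytest.approx(5.2898, abs=1e-3)

    def test_nonpositive_height_rejected(self, mean_leg):
        with pytest.raises(PlanningError):
            medial_entry(mean_leg, 0.0)


class TestWedgeWidth:
    def test_zero_angle_zero_width(self):
        assert wedge_width(75.0, 0.0) == 0.0

    def test_closed_form_value(self):
        assert wedge_width(75.0, 7.0) == pytest.approx(
            2 * 75 * math.sin(math.radians(3.5)), rel=1e-12)
        assert wedge_width(75.0, 7.0) == pytest.approx(9.1573, abs=1e-3)

    @given(L=st.floats(10, 120), alpha=st.floats(0, 30))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_length(self, L, alpha):
        assert wedge_width(2 * L, alpha) == pytest.approx(
            2 * wedge_width(L, alpha), rel=1e-12)

    def test_negative_length_rejected(self):
        with pytest.raises(PlanningError):
            wedge_width(-1.0, 5.0)


class TestSolver:
    def test_already_at_target_returns_zero(self):
        leg = make_leg(-2.0, 475.0, 372.6, 79.5)  # valgus limb
        hinge = hinge_point(leg, 15.0)
        with pytest.warns(AlreadyCorrectedWarning):
            alpha = solve_correction_angle(leg, hinge)
        assert alpha == 0.0

    def test_strict_mode_raises_instead(self):
        leg = make_leg(-2.0, 475.0, 372.6, 79.5)
        hinge = hinge_point(leg, 15.0)
        with pytest.raises(PlanningError):
            solve_correction_angle(leg, hinge, config=PlannerConfig(strict=True))

    def test_no_solution_error_for_extreme_target(self, mean_leg):
        hinge = hinge_point(mean_leg, 15.0)
        with pytest.raises(NoSolutionError):
            solve_correction_angle(mean_leg, hinge, target_fraction=5.0)

    @pytest.mark.parametrize("varus,hinge_mm", [(3, 5), (6, 15), (12, 10), (17, 5)])
    def test_fixed_point(self, varus, hinge_mm):
        leg = make_leg(varus, 475.0, 372.6, 79.5)
        hinge = hinge_point(leg, hinge_mm)
        alpha = solve_correction_angle(leg, hinge)
        rotated = rotate_distal(leg, hinge, math.radians(alpha))
        assert wbl_fraction(rotated) == pytest.approx(0.55, abs=1e-8)

    @pytest.mark.parametrize("varus,hinge_mm", [(4, 5), (6, 15), (13, 10)])
    def test_grid_search_oracle_agreement(self, varus, hinge_mm):
        leg = make_leg(varus, 475.0, 372.6, 79.5)
        hinge = hinge_point(leg, hinge_mm)
        alpha = solve_correction_angle(leg, hinge)
        assert alpha == pytest.approx(grid_search_alpha(leg, hinge), abs=0.002)

    @given(varus=st.floats(3, 17), hinge_mm=st.floats(3, 20),
           width=st.floats(65, 95))
    @settings(max_examples=60, deadline=None)
    def test_circle_line_oracle_agreement(self, varus, hinge_mm, width):
        leg = make_leg(varus, 475.0, 372.6, width)
        hinge = hinge_point(leg, hinge_mm)
        alpha = solve_correction_angle(leg, hinge)
        assert alpha == pytest.approx(circle_line_alpha(leg, hinge), abs=1e-7)


class TestPlanOsteotomy:
    def test_fig3_style_worked_case(self, mean_leg):
        """6 deg varus, entry 40 mm, hinge 15 mm: wedge near 8.7 mm."""
        plan = plan_osteotomy(mean_leg, 40.0, 15.0)
        assert plan.condition_label == "4cm-C"
        assert plan.wedge_width == pytest.approx(8.7, abs=1.0)
        assert plan.achieved_fraction == pytest.approx(0.55, abs=1e-8)

    @given(varus=st.floats(3, 17), hinge_mm=st.sampled_from([5.0, 10.0, 15.0]),
           height=st.sampled_from([30.0, 40.0]))
    @settings(max_examples=60, deadline=None)
    def test_chord_identity_on_all_plans(self, varus, hinge_mm, height):
        leg = make_leg(varus, 475.0, 372.6, 79.5)
        plan = plan_osteotomy(leg, height, hinge_mm)
        chord = 2 * plan.osteotomy_length * math.sin(
            math.radians(plan.correction_angle) / 2)
        assert plan.wedge_width == pytest.approx(chord, abs=1e-12)

    def test_height_insensitivity(self, mean_leg):
        w30 = plan_osteotomy(mean_leg, 30.0, 5.0).wedge_width
        w40 = plan_osteotomy(mean_leg, 40.0, 5.0).wedge_width
        assert abs(w40 - w30) < 0.5

    def test_wedge_decreases_as_hinge_moves_medially(self, mean_leg):
        """Shorter cut at an essentially unchanged correction angle gives a
        narrower medial gap (chord scales with osteotomy length)."""
        w = [plan_osteotomy(mean_leg, 30.0, d).wedge_width for d in (5, 10, 15)]
        assert w[0] > w[1] > w[2]

    def test_alpha_insensitive_to_hinge_position(self, mean_leg):
        alphas = [plan_osteotomy(mean_leg, 30.0, d).correction_angle
                  for d in (5, 10, 15)]
        assert max(alphas) - min(alphas) < 0.3

    def test_wedge_monotone_in_target_and_varus(self):
        leg = make_leg(6.0, 475.0, 372.6, 79.5)
        w_t = [plan_osteotomy(leg, 30, 5, PlannerConfig(target_fraction=f)).wedge_width
               for f in (0.50, 0.55, 0.60)]
        assert w_t[0] < w_t[1] < w_t[2]
        w_v = [plan_osteotomy(make_leg(v, 475.0, 372.6, 79.5), 30, 5).wedge_width
               for v in (3, 6, 9, 12)]
        assert all(a < b for a, b in zip(w_v, w_v[1:]))

    @given(varus=st.floats(3, 17))
    @settings(max_examples=40, deadline=None)
    def test_mirror_yields_identical_plan(self, varus):
        leg = make_leg(varus, 475.0, 372.6, 79.5)
        p_r = plan_osteotomy(leg, 40.0, 10.0)
        p_l = plan_osteotomy(mirrored(leg), 40.0, 10.0)
        assert p_l.correction_angle == pytest.approx(p_r.correction_angle, abs=1e-9)
        assert p_l.wedge_width == pytest.approx(p_r.wedge_width, abs=1e-9)

    def test_saw_kerf_is_additive(self, mean_leg):
        w0 = plan_osteotomy(mean_leg, 30.0, 5.0).wedge_width
        w1 = plan_osteotomy(mean_leg, 30.0, 5.0,
                            PlannerConfig(saw_kerf_mm=1.2)).wedge_width
        assert w1 == pytest.approx(w0 + 1.2, abs=1e-12)


class TestApplyWedge:
    def test_replanned_wedge_at_more_lateral_hinge_undercorrects(self, mean_leg):
        """Opening the hinge-15-planned wedge at hinge 5 gives a longer cut,
        hence a smaller angle, hence an achieved WBL short of 55%."""
        planned = plan_osteotomy(mean_leg, 40.0, 15.0)
        res = apply_wedge(mean_leg, 40.0, 5.0, planned.wedge_width)
        assert res["achieved_fraction"] < 0.55
        assert res["correction_angle"] < planned.correction_angle

    def test_same_hinge_round_trip(self, mean_leg):
        planned = plan_osteotomy(mean_leg, 40.0, 15.0)
        res = apply_wedge(mean_leg, 40.0, 15.0, planned.wedge_width)
        assert res["achieved_fraction"] == pytest.approx(0.55, abs=1e-9)

    def test_overlarge_wedge_rejected(self, mean_leg):
        with pytest.raises(PlanningError):
            apply_wedge(mean_leg, 40.0, 15.0, 500.0)
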