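"""Curvature estimation, angle conversion, branch angles, segment stats."""

import numpy as np
import pytest

from strandscope import (
    AngleModel,
    StrandTrace,
    angle_per_monomer,
    arcfit_curvature,
    branch_angle,
    branch_angle_modes,
    curvature_summary,
    discontinuity_rate,
    segment_stats,
)
from strandscope.curvature import (
    KINK_TURN_DEG,
    _pratt_circle,
    _tangent_at,
    tangent_correlation_length,
)
from strandscope.synthetic import trace_from_arcs

from conftest import circle_points


# -- angle conversion (closed form) ---------------------------------------


class TestAnglePerMonomer:
    def test_arc_mode_linear(self):
        model = AngleModel(2.8, "arc")
        # theta = d * kappa exactly
        assert angle_per_monomer(8.0, model) == pytest.approx(
            np.degrees(2.8 * 8.0e-3)
        )

    def test_median_value_rounds_to_1_3(self):
        assert round(angle_per_monomer(8.0, AngleModel(2.8, "arc")), 1) == 1.3

    def test_extreme_value_both_modes_round_to_20(self):
        arc = angle_per_monomer(123.0, AngleModel(2.8, "arc"))
        chord = angle_per_monomer(123.0, AngleModel(2.8, "chord"))
        assert arc == pytest.approx(19.73, abs=0.005)
        assert chord == pytest.approx(19.83, abs=0.005)
        assert round(arc) == round(chord) == 20

    def test_chord_exceeds_arc_never(self):
        kappas = np.linspace(0.1, 123.0, 50)
        arc = angle_per_monomer(kappas, AngleModel(2.8, "arc"))
        chord = angle_per_monomer(kappas, AngleModel(2.8, "chord"))
        # chord turn is always >= arc angle for the same kappa
        assert np.all(chord >= arc - 1e-12)
        assert np.max(chord - arc) < 0.11

    def test_monotone_in_kappa(self):
        for mode in ("arc", "chord"):
            vals = angle_per_monomer(
                np.linspace(0, 100, 30), AngleModel(2.8, mode)
            )
            assert np.all(np.diff(vals) > 0)

    def test_zero_kappa_gives_zero(self):
        assert angle_per_monomer(0.0) == 0.0

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            angle_per_monomer(-1.0)

    def test_chord_mode_domain_error(self):
        # d * kappa / 2 > 1 requires kappa > 2/d; d = 2.8 nm -> ~714286 /um
        with pytest.raises(ValueError, match="chord mode"):
            angle_per_monomer(8.0e5, AngleModel(2.8, "chord"))

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            AngleModel(2.8, "secant")


# -- circle oracle ---------------------------------------------------------


class TestArcfitCircleOracle:
    @pytest.mark.parametrize("radius_nm", [8.13, 125.0, 1000.0])
    @pytest.mark.parametrize("phase", [0.0, 0.37, 1.9, 4.4])
    def test_exact_circles(self, radius_nm, phase):
        pts = circle_points(radius_nm, n=400, phase=phase)
        tr = StrandTrace(pts, 1.2, "circle")
        prof = arcfit_curvature(tr, window=10)
        true = 1000.0 / radius_nm  # 1/um
        rel = np.abs(prof.kappa - true) / true
        assert len(prof) > 100
        assert rel.max() < 1e-6

    def test_straight_line_zero(self):
        pts = np.column_stack([np.arange(100) * 1.2, np.zeros(100)])
        prof = arcfit_curvature(StrandTrace(pts, 1.2, "line"))
        assert np.all(prof.kappa == 0.0)

    def test_signed_kappa_tracks_turn_direction(self):
        left = circle_points(100.0, 300)  # counter-clockwise
        prof_l = arcfit_curvature(StrandTrace(left, 1.2, "l"))
        prof_r = arcfit_curvature(StrandTrace(left[::-1].copy(), 1.2, "r"))
        assert np.all(prof_l.kappa_signed > 0)
        assert np.all(prof_r.kappa_signed < 0)

    def test_rotation_translation_invariance(self):
        pts = circle_points(50.0, 250, phase=0.2)
        tr = StrandTrace(pts, 1.2, "c")
        moved = tr.transformed(rotation_deg=73.0, translation=(40.0, -7.0))
        k0 = arcfit_curvature(tr).kappa
        k1 = arcfit_curvature(moved).kappa
        # arc-length rounding may add/drop one trailing sample
        m = min(len(k0), len(k1))
        assert abs(len(k0) - len(k1)) <= 1
        assert np.max(np.abs(k1[:m] - k0[:m]) / k0[:m]) < 1e-6

    def test_short_trace_warns_and_returns_empty(self):
        pts = np.column_stack([np.arange(5) * 1.2, np.zeros(5)])
        with pytest.warns(UserWarning, match="too short"):
            prof = arcfit_curvature(StrandTrace(pts, 1.2, "short"), window=10)
        assert len(prof) == 0

    def test_kink_flag_raised_at_discrete_bend(self):
        tr = trace_from_arcs(
            [(120.0, 0.0), (120.0, 0.0)], bend_angles_deg=[60.0]
        )
        prof = arcfit_curvature(tr, window=10)
        assert prof.kink_flag.any()
        # flagged samples cluster at the joint (arc position ~120 nm)
        flagged = prof.positions[prof.kink_flag]
        assert np.all(np.abs(flagged - 120.0) < 15.0)

    def test_smoothing_preserves_circle_curvature(self):
        pts = circle_points(125.0, 500)  # kappa = 8 / um
        prof = arcfit_curvature(StrandTrace(pts, 1.2, "c"), smooth_px=35)
        true = 8.0
        assert np.abs(np.median(prof.kappa) - true) / true < 5e-3

    def test_invalid_window_rejected(self):
        pts = circle_points(50.0, 100)
        with pytest.raises(ValueError, match="window"):
            arcfit_curvature(StrandTrace(pts, 1.2), window=0)


# -- summary ---------------------------------------------------------------


class TestCurvatureSummary:
    def test_known_mixture(self):
        # two circles with exactly known kappa: 5 and 20 / um
        profs = [
            arcfit_curvature(StrandTrace(circle_points(200.0, 300), 1.2, "a")),
            arcfit_curvature(StrandTrace(circle_points(50.0, 300), 1.2, "b")),
        ]
        s = curvature_summary(profs, AngleModel(2.8, "arc"))
        assert s["n_strands"] == 2
        assert s["max_kappa_per_um"] == pytest.approx(20.0, rel=1e-6)
        # equal sample counts -> median halfway between the two values
        assert 5.0 < s["median_kappa_per_um"] < 20.0
        assert s["median_angle_deg"] == pytest.approx(
            angle_per_monomer(s["median_kappa_per_um"]), rel=1e-12
        )
        # histogram counts sum to sample count
        assert sum(s["histogram_counts"]) == s["n_samples"]

    def test_fraction_above_threshold_boundary_strict(self):
        # a constructed profile whose samples sit exactly at the threshold
        # angle: strict > must exclude every one of them
        from strandscope import CurvatureProfile

        model = AngleModel(2.8, "arc")
        kappa_at_3deg = np.deg2rad(3.0) / 2.8 * 1000.0
        assert angle_per_monomer(kappa_at_3deg, model) == pytest.approx(3.0)
        prof = CurvatureProfile(
            positions=np.arange(10, dtype=float),
            kappa=np.full(10, kappa_at_3deg),
            window=10,
            step=1,
        )
        s = curvature_summary([prof], model, 3.0)
        assert s["fraction_angle_above_threshold"] == 0.0
        # nudging kappa up by 1 ppm flips all samples above the threshold
        prof_hi = CurvatureProfile(
            positions=np.arange(10, dtype=float),
            kappa=np.full(10, kappa_at_3deg * (1 + 1e-6)),
            window=10,
            step=1,
        )
        s_hi = curvature_summary([prof_hi], model, 3.0)
        assert s_hi["fraction_angle_above_threshold"] == 1.0

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            curvature_summary([])


# -- tangent fit and branch angles ----------------------------------------


class TestPrattCircle:
    def test_recovers_exact_circle(self):
        th = np.linspace(0.1, 1.4, 40)
        pts = np.column_stack([3 + 77 * np.cos(th), -9 + 77 * np.sin(th)])
        a, b, c, d = _pratt_circle(pts)
        assert -b / (2 * a) == pytest.approx(3.0, abs=1e-6)
        assert -c / (2 * a) == pytest.approx(-9.0, abs=1e-6)
        radius = np.sqrt(b * b + c * c - 4 * a * d) / (2 * abs(a))
        assert radius == pytest.approx(77.0, abs=1e-6)

    def test_line_limit(self):
        pts = np.column_stack([np.linspace(0, 30, 20), np.linspace(0, 10, 20)])
        coef = _pratt_circle(pts)
        t = _tangent_at(pts, 0)
        d = np.array([3.0, 1.0]) / np.sqrt(10.0)
        assert coef is not None
        assert abs(t @ d) == pytest.approx(1.0, abs=1e-9)

    def test_tangent_extrapolation_along_circle(self):
        th = np.linspace(0.5, 1.2, 30)
        radius = 60.0
        pts = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
        # tangent at arc position 10 nm before the first point
        t = _tangent_at(pts, 0, eval_offset_nm=-10.0)
        th_eval = th[0] - 10.0 / radius
        expected = np.array([-np.sin(th_eval), np.cos(th_eval)])
        assert abs(t @ expected) == pytest.approx(1.0, abs=1e-9)


class TestBranchAngle:
    def _straight(self, n, px=1.2):
        return np.column_stack([np.arange(n) * px, np.zeros(n)])

    def _branch_from(self, start, ang_deg, n=150, px=1.2):
        th = np.deg2rad(ang_deg)
        return start + np.outer(np.arange(n) * px, [np.cos(th), np.sin(th)])

    def test_right_angle_exact(self):
        par = StrandTrace(self._straight(400), 1.2, "p")
        bra = StrandTrace(self._branch_from(par.points[200], 90.0), 1.2, "b")
        assert branch_angle(par, bra).angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_67_degrees_within_half_degree(self):
        par = StrandTrace(self._straight(400), 1.2, "p")
        bra = StrandTrace(self._branch_from(par.points[200], 67.0), 1.2, "b")
        assert branch_angle(par, bra).angle_deg == pytest.approx(67.0, abs=0.5)

    def test_obtuse_nominal_folds_to_acute(self):
        par = StrandTrace(self._straight(400), 1.2, "p")
        bra = StrandTrace(self._branch_from(par.points[200], 113.0), 1.2, "b")
        assert branch_angle(par, bra).angle_deg == pytest.approx(67.0, abs=0.5)

    def test_curved_parent_and_branch_exact(self):
        # parent: circle kappa=10 /um; branch leaves its midpoint at 67 deg
        par = trace_from_arcs([(600.0, 10.0)], strand_id="p")
        mid = len(par) // 2
        # local tangent of the parent at the midpoint
        t = par.points[mid + 1] - par.points[mid - 1]
        base = np.arctan2(t[1], t[0])
        th = base + np.deg2rad(67.0)
        bra_pts = par.points[mid] + np.outer(
            np.arange(150) * 1.2, [np.cos(th), np.sin(th)]
        )
        m = branch_angle(par, StrandTrace(bra_pts, 1.2, "b"))
        assert m.angle_deg == pytest.approx(67.0, abs=0.3)

    def test_rigid_invariance(self):
        par = StrandTrace(self._straight(400), 1.2, "p")
        bra = StrandTrace(self._branch_from(par.points[200], 67.0), 1.2, "b")
        a0 = branch_angle(par, bra).angle_deg
        a1 = branch_angle(
            par.transformed(41.0, (12.0, -3.0)),
            bra.transformed(41.0, (12.0, -3.0)),
        ).angle_deg
        assert abs(a1 - a0) < 1e-6

    def test_disjoint_traces_rejected(self):
        par = StrandTrace(self._straight(100), 1.2, "p")
        bra = StrandTrace(self._straight(100) + [0.0, 50.0], 1.2, "b")
        with pytest.raises(ValueError, match="intersect"):
            branch_angle(par, bra)

    def test_junction_is_branch_endpoint_not_recrossing(self):
        # branch starts at the parent at 90 deg, then curves back and
        # crosses the parent again downstream; the measured angle must
        # reflect the planted 90 deg start, not the re-crossing
        par = StrandTrace(self._straight(800), 1.2, "p")
        bra = trace_from_arcs(
            [(500.0, -15.0)], start=par.points[100], heading_deg=90.0,
            strand_id="b",
        )
        # confirm the branch really does come back near the parent line
        assert np.min(np.abs(bra.points[200:, 1])) < 2.0
        m = branch_angle(par, bra)
        assert m.angle_deg == pytest.approx(90.0, abs=1.0)
        assert np.linalg.norm(m.junction - par.points[100]) < 2.5

    def test_invalid_window_rejected(self):
        par = StrandTrace(self._straight(100), 1.2, "p")
        with pytest.raises(ValueError, match="tangent_window"):
            branch_angle(par, par, tangent_window=1)


class TestBranchAngleModes:
    def test_separated_gaussian_mixture(self):
        rng = np.random.default_rng(11)
        sample = np.concatenate(
            [rng.normal(45.0, 2.0, 400), rng.normal(75.0, 2.0, 400)]
        )
        sample = np.clip(sample, 0.0, 90.0)
        modes = branch_angle_modes(sample)
        assert modes[0] == pytest.approx(45.0, abs=1.0)
        assert modes[1] == pytest.approx(75.0, abs=1.0)

    def test_boundary_mode_at_90_not_pulled_inward(self):
        rng = np.random.default_rng(4)
        # acute-folded normal at 90: all mass reflects below 90
        raw = rng.normal(90.0, 3.0, 800)
        folded = 90.0 - np.abs(raw - 90.0)
        modes = branch_angle_modes(folded, n_modes=1)
        assert modes[0] == pytest.approx(90.0, abs=1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="acute"):
            branch_angle_modes([30.0, 95.0])

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError, match="at least two"):
            branch_angle_modes([45.0])


# -- segments, breaks, persistence ----------------------------------------


class TestSegmentsAndBreaks:
    def test_segment_stats_known_values(self):
        segs = [
            StrandTrace(np.array([[0.0, 0.0], [100.0, 0.0]]), 1.2, "s1"),
            StrandTrace(np.array([[0.0, 0.0], [300.0, 0.0]]), 1.2, "s2"),
        ]
        s = segment_stats(segs)
        assert s["n"] == 2
        assert s["mean_nm"] == pytest.approx(200.0)
        assert s["sd_nm"] == pytest.approx(np.std([100, 300], ddof=1))

    def test_segment_stats_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            segment_stats([])

    def test_discontinuity_rate_counts_transitions(self):
        n = 1000  # ~1.2 um at 1.2 nm steps
        pts = np.column_stack([np.arange(n) * 1.2, np.zeros(n)])
        face = np.array(["P"] * 400 + ["E"] * 300 + ["P"] * 300, dtype=object)
        tr = StrandTrace(pts, 1.2, "t", face)
        rate = discontinuity_rate(tr)
        assert rate == pytest.approx(2.0 / (tr.arc_length / 1000.0))

    def test_discontinuity_requires_labels(self):
        pts = np.column_stack([np.arange(10) * 1.2, np.zeros(10)])
        with pytest.raises(ValueError, match="face"):
            discontinuity_rate(StrandTrace(pts, 1.2, "t"))

    def test_length_window_warning(self):
        pts = np.column_stack([np.arange(100) * 1.2, np.zeros(100)])
        tr = StrandTrace(pts, 1.2, "short", np.array(["P"] * 100, dtype=object))
        with pytest.warns(UserWarning, match="counting window"):
            discontinuity_rate(tr)

    def test_persistence_length_of_wlc(self):
        # discrete worm-like chain with Lp = 250 nm (2-D convention)
        rng = np.random.default_rng(8)
        lp, ds, n = 250.0, 1.2, 20000
        theta = np.cumsum(rng.normal(0.0, np.sqrt(ds / lp), n))
        pts = np.cumsum(
            np.column_stack([np.cos(theta), np.sin(theta)]) * ds, axis=0
        )
        est = tangent_correlation_length(
            StrandTrace(pts, 1.2, "wlc"), max_lag_nm=400.0
        )
        assert est == pytest.approx(lp, rel=0.25)
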