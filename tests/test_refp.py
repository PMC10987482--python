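"""REFP estimation: IQR fencing, curves, alignment, pooled profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import make_smoothing_spline

from refplane.refp import (AlignmentError, CurveError, PooledProfile,
                           align_curves, build_pooled_profile,
                           build_sweep_curve, compute_refp, feature_refp,
                           iqr_filter)


class TestIqrFilter:
    def test_hand_computed_example(self):
        # Q1=2, Q3=4 under linear interpolation, fences [-1, 7]
        keep = iqr_filter([1, 2, 3, 4, 100])
        assert keep.tolist() == [True, True, True, True, False]

    def test_all_equal_kept(self):
        assert iqr_filter([5.0] * 8).all()

    def test_fewer_than_four_kept_by_policy(self):
        assert iqr_filter([1.0, 50.0, -99.0]).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=40),
           st.floats(0.5, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_fences_match_definition(self, values, k):
        keep = iqr_filter(values, k=k)
        q1, q3 = np.quantile(values, [0.25, 0.75])
        lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
        for v, kept in zip(values, keep):
            assert kept == (lo <= v <= hi)


def curve_frame(z, ss, ci, sat=None):
    sat = sat if sat is not None else np.zeros(len(z), bool)
    return pd.DataFrame({
        "z_um": z, "median_ss": ss, "median_ci": ci,
        "sat_ss": sat, "sat_ci": sat, "n_ss": 8, "n_ci": 8,
    })


def template_ci(z, center=1500.0, width=28.0):
    return 1.0 + 0.8 / (1.0 + ((z - center) / width) ** 2)


class TestBuildSweepCurve:
    def make_features(self, z_levels, beads_per_z=7, outlier=False, sat_at=()):
        rows = []
        rng = np.random.default_rng(0)
        for z in z_levels:
            for b in range(beads_per_z):
                ss = -0.2 + 0.001 * rng.normal()
                if outlier and b == 0:
                    ss += 5.0  # gross outlier
                rows.append({
                    "experiment": "e", "exposure_ms": 9.0, "fov": 0,
                    "z_um": z, "bead_id": b, "ss": ss,
                    "ci": 1.5 + 0.001 * rng.normal(),
                    "saturated_count": 3 if z in sat_at else 0,
                })
        return pd.DataFrame(rows)

    def test_outliers_do_not_move_median(self):
        z = np.arange(1480.0, 1530.0, 7.5)
        clean = build_sweep_curve(self.make_features(z))
        dirty = build_sweep_curve(self.make_features(z, outlier=True))
        diff = np.abs(clean.points.median_ss - dirty.points.median_ss)
        assert diff.max() < 0.005

    def test_saturation_flag_marks_exact_levels(self):
        z = np.arange(1480.0, 1530.0, 7.5)
        curve = build_sweep_curve(self.make_features(z, sat_at=(z[2], z[3])))
        assert curve.points.sat_ci.tolist() == [
            zi in (z[2], z[3]) for zi in curve.points.z_um
        ]

    def test_even_count_flag_is_or_of_middle_beads(self):
        rows = []
        for b, (ss, sat) in enumerate(
                [(-0.3, 0), (-0.25, 0), (-0.2, 5), (-0.15, 0)] * 1):
            rows.append({"experiment": "e", "exposure_ms": 9.0, "fov": 0,
                         "z_um": 1500.0, "bead_id": b, "ss": ss, "ci": 1.0,
                         "saturated_count": sat})
        for z in (1507.5, 1515.0):  # pad to 3 usable Z levels
            for b in range(4):
                rows.append({"experiment": "e", "exposure_ms": 9.0, "fov": 0,
                             "z_um": z, "bead_id": b, "ss": -0.2, "ci": 1.0,
                             "saturated_count": 0})
        curve = build_sweep_curve(pd.DataFrame(rows))
        # middle beads by ss at z=1500 are -0.25 and -0.2; the -0.2 bead saturates
        assert bool(curve.points.iloc[0].sat_ss) is True

    def test_too_few_levels_fails(self):
        with pytest.raises(CurveError):
            build_sweep_curve(self.make_features([1500.0, 1507.5]))


class TestAlignCurves:
    def make_spline(self, z, y):
        return make_smoothing_spline(z, y)

    def test_identity_alignment(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        y = template_ci(z)
        sp = self.make_spline(z, y)
        shift, scale, _ = align_curves(sp, (z.min(), z.max()), z, y, 7.5)
        assert abs(shift) <= 0.5
        assert scale == pytest.approx(1.0, abs=0.01)

    def test_recovers_constructed_shift_and_scale(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        sp = self.make_spline(z, template_ci(z))
        fixed_y = 1.2 * template_ci(z - 30.0)
        shift, scale, _ = align_curves(sp, (z.min(), z.max()), z, fixed_y, 7.5,
                                       shift_halfwidth=60.0)
        assert shift == pytest.approx(30.0, abs=0.5)
        assert scale == pytest.approx(1.2, abs=0.01)

    def test_saturated_points_excluded_without_breaking_alignment(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        sp = self.make_spline(z, template_ci(z))
        yt = template_ci(z - 15.0)
        sat = np.abs(z - 1515.0) < 8.0  # clip the two points nearest the peak
        shift_clean, _, _ = align_curves(sp, (z.min(), z.max()), z, yt, 7.5,
                                         shift_halfwidth=45.0)
        shift_sat, _, _ = align_curves(sp, (z.min(), z.max()), z[~sat], yt[~sat],
                                       7.5, shift_halfwidth=45.0)
        assert abs(shift_sat - shift_clean) <= 7.5

    def test_too_few_points_fails(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        sp = self.make_spline(z, template_ci(z))
        with pytest.raises(AlignmentError):
            align_curves(sp, (z.min(), z.max()), z[:3], template_ci(z[:3]), 7.5)

    def test_composition_of_shifts(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        sp = self.make_spline(z, template_ci(z))
        y_b = template_ci(z - 15.0)
        y_c = template_ci(z - 37.5)
        s_ab, _, _ = align_curves(sp, (z.min(), z.max()), z, y_b, 7.5, 60.0)
        sp_b = self.make_spline(z, y_b)
        s_bc, _, _ = align_curves(sp_b, (z.min(), z.max()), z, y_c, 7.5, 60.0)
        s_ac, _, _ = align_curves(sp, (z.min(), z.max()), z, y_c, 7.5, 60.0)
        assert s_ab + s_bc == pytest.approx(s_ac, abs=1.0)


class TestPooledProfile:
    def make_curves(self, shifts, scales, sat_masks=None):
        z = np.arange(1440.0, 1560.1, 7.5)
        curves = []
        for i, (sh, sc) in enumerate(zip(shifts, scales)):
            ci = sc * template_ci(z - sh)
            ss = -sc * (template_ci(z - sh) - 1.0) - 0.01
            sat = sat_masks[i] if sat_masks else np.zeros(len(z), bool)
            frame = curve_frame(z, ss, ci, sat)
            curves.append(type("C", (), {})())
            from refplane.refp import SweepCurve

            curves[-1] = SweepCurve(key=("e", float(6 + 3 * i), 0), points=frame)
        return z, curves

    def test_single_curve_pool_is_identity(self):
        z, curves = self.make_curves([0.0], [1.0])
        pooled = build_pooled_profile(curves[:1], "ci", 7.5)
        shift, scale = pooled.alignments[curves[0].key]
        assert abs(shift) <= 0.5 and scale == pytest.approx(1.0, abs=0.01)

    def test_transformed_copies_recover_construction(self):
        shifts = [0.0, 7.5, -15.0, 22.5, -30.0, 15.0]
        z, curves = self.make_curves(shifts, [1.0, 1.1, 0.9, 1.2, 0.95, 1.05])
        pooled = build_pooled_profile(curves, "ci", 7.5, reference_key=curves[0].key)
        rec = [pooled.alignments[c.key][0] for c in curves]
        for got, (s0, s) in zip(rec, zip([shifts[0]] * 6, shifts)):
            assert got == pytest.approx(-(s - shifts[0]), abs=0.5) or \
                got == pytest.approx(s0 - s, abs=0.5)

    def test_saturated_points_absent_from_pool(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        sat = np.abs(z - 1500.0) < 8.0
        _, curves = self.make_curves([0.0, 0.0], [1.0, 1.0],
                                     sat_masks=[np.zeros(len(z), bool), sat])
        pooled = build_pooled_profile(curves, "ci", 7.5,
                                      reference_key=curves[0].key)
        # pooled spline was fit without the saturated points: it still has a
        # single interior maximum near the template peak
        grid = np.linspace(*pooled.domain, 400)
        peak = grid[np.argmax(pooled(grid))]
        assert abs(peak - 1500.0) < 4.0


class TestFeatureRefp:
    def test_peak_location_on_exact_curve(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        from refplane.refp import SweepCurve

        ci = template_ci(z, center=1503.0)
        curve = SweepCurve(key=("e", 9.0, 0),
                           points=curve_frame(z, -ci, ci))
        pooled = build_pooled_profile([curve], "ci", 7.5)
        refp, boundary = feature_refp(pooled, curve, 7.5)
        assert refp == pytest.approx(1503.0, abs=3.75)
        assert not boundary

    def test_boundary_warning_when_extremum_at_edge(self):
        z = np.arange(1440.0, 1560.1, 7.5)
        from refplane.refp import SweepCurve

        ci = template_ci(z, center=1557.0)  # peak at the sweep edge
        curve = SweepCurve(key=("e", 9.0, 0), points=curve_frame(z, -ci, ci))
        pooled = build_pooled_profile([curve], "ci", 7.5)
        refp, boundary = feature_refp(pooled, curve, 7.5)
        assert boundary


class TestComputeRefp:
    @pytest.mark.parametrize("ss,ci,expected", [
        (1500.0, 1515.0, 1507.5),
        (1507.5, 1507.5, 1507.5),
        (1380.0, 1620.0, 1500.0),
    ])
    def test_arithmetic_mean(self, ss, ci, expected):
        assert compute_refp(ss, ci) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_refp(np.nan, 1500.0)
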