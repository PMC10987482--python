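"""Reference effective focal plane (REFP) estimation from pooled feature curves.

The REFP of a Z sweep is the stage position at which the reference beads
are most in focus.  It is estimated from the two radial-profile features:
the steepest slope SS (most negative at focus) and the center intensity CI
(maximal at focus).  The procedure, per (experiment, exposure, FOV):

1. for each Z, remove per-bead outliers by interquartile-range fencing and
   take the median feature value; record whether the median bead image(s)
   contain saturated pixels,
2. fit a smoothing spline to each median-vs-Z curve,
3. align every curve to one chosen reference curve, allowing an additive
   shift in Z and a multiplicative rescaling of the feature, and fit one
   smoothing spline to the pooled, aligned points ("pooled profile"),
4. fit the pooled profile back to each curve's unsaturated points
   (shift + scale again) and read off the Z of the profile extremum:
   REFP_SS at the SS minimum, REFP_CI at the CI maximum,
5. REFP = (REFP_SS + REFP_CI) / 2.

Saturation is handled per point, not per curve: medians whose middle bead
image(s) clip at 255 are excluded from spline fitting and alignment, so a
sweep whose high-exposure images saturate near focus still yields a REFP
from its clean flanks plus the pooled shape.

Quartiles use linear interpolation between order statistics (the numpy
default); the IQR fence multiplier is k = 1.5 with two-sided fences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar

KEY = ["experiment", "exposure_ms", "fov"]


class CurveError(RuntimeError):
    """Raised when a sweep curve cannot be built."""


class AlignmentError(RuntimeError):
    """Raised when a curve cannot be aligned to the reference."""


@dataclass
class SweepCurve:
    """Median feature values vs. Z for one (experiment, exposure, FOV)."""

    key: tuple
    points: pd.DataFrame  # z_um, median_ss, median_ci, sat_ss, sat_ci, n_ss, n_ci

    def feature_points(self, feature: str, unsaturated_only: bool = True):
        z = self.points["z_um"].to_numpy(float)
        y = self.points[f"median_{feature}"].to_numpy(float)
        sat = self.points[f"sat_{feature}"].to_numpy(bool)
        if unsaturated_only:
            return z[~sat], y[~sat]
        return z, y


@dataclass
class PooledProfile:
    """Smoothing-spline template of a feature vs. effective focal plane."""

    feature: str
    reference_key: tuple
    spline: object  # callable z -> feature value, valid on `domain`
    domain: tuple[float, float]
    alignments: dict  # key -> (shift_um, scale)

    def __call__(self, z):
        return self.spline(z)


@dataclass
class RefpEstimate:
    key: tuple
    refp_ss: float
    refp_ci: float
    refp_final: float
    boundary_warning: bool = False


def iqr_filter(values, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values inside [Q1 - k*IQR, Q3 + k*IQR].

    With fewer than 4 values the quartiles are too unstable to fence on and
    everything is kept.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("iqr_filter needs at least one value")
    if values.size < 4:
        return np.ones(values.shape, dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


def _median_flags(values: np.ndarray, saturated: np.ndarray) -> tuple[float, bool, int]:
    """Median after IQR fencing plus the saturation flag of the median bead(s).

    With an even count the median is the mean of the two middle values and
    the flag is the OR of those two beads' saturation (conservative).
    """
    keep = iqr_filter(values)
    v = values[keep]
    s = saturated[keep]
    order = np.argsort(v, kind="stable")
    n = v.size
    if n % 2:
        mid = [order[n // 2]]
    else:
        mid = [order[n // 2 - 1], order[n // 2]]
    return float(np.median(v)), bool(np.any(s[mid])), int(n)


def build_sweep_curve(group: pd.DataFrame) -> SweepCurve:
    """Build the median SS / CI curve for one (experiment, exposure, FOV).

    ``group`` is the slice of the features table for that key; needs at
    least 3 Z levels with at least one bead each.
    """
    key = tuple(group.iloc[0][KEY])
    rows = []
    for z, g in group.groupby("z_um", sort=True):
        sat = (g["saturated_count"].to_numpy(int) > 0)
        m_ss, f_ss, n_ss = _median_flags(g["ss"].to_numpy(float), sat)
        m_ci, f_ci, n_ci = _median_flags(g["ci"].to_numpy(float), sat)
        rows.append({"z_um": float(z), "median_ss": m_ss, "median_ci": m_ci,
                     "sat_ss": f_ss, "sat_ci": f_ci, "n_ss": n_ss, "n_ci": n_ci})
    if len(rows) < 3:
        raise CurveError(f"curve {key}: only {len(rows)} usable Z levels")
    return SweepCurve(key=key, points=pd.DataFrame(rows))


def _curve_spline(z: np.ndarray, y: np.ndarray):
    """GCV smoothing spline through a median feature curve."""
    if z.size < 4:
        raise CurveError("need at least 4 points for a curve spline")
    return make_smoothing_spline(z, y)


def align_curves(
    moving,
    moving_domain: tuple[float, float],
    fixed_z: np.ndarray,
    fixed_y: np.ndarray,
    z_increment: float,
    shift_halfwidth: float | None = None,
) -> tuple[float, float, float]:
    """Least-squares fit of ``scale * moving(z - shift)`` to fixed points.

    Nested optimization: a grid search over the shift at z_increment / 4
    resolution with the closed-form optimal scale at each shift, followed
    by a local refinement.  Only fixed points falling inside the shifted
    domain of ``moving`` participate; at least 4 (and at least half of the
    fixed points) are required for a shift to be admissible.

    Returns (shift_um, scale, rms_residual).
    """
    fixed_z = np.asarray(fixed_z, float)
    fixed_y = np.asarray(fixed_y, float)
    if fixed_z.size < 4:
        raise AlignmentError("need at least 4 unsaturated fixed points")
    lo, hi = moving_domain
    if shift_halfwidth is None:
        span = fixed_z.max() - fixed_z.min()
        shift_halfwidth = max(span / 2.0, 2 * z_increment)
    min_pts = max(4, fixed_z.size // 2)

    def cost(shift: float) -> tuple[float, float]:
        zm = fixed_z - shift
        ok = (zm >= lo) & (zm <= hi)
        if ok.sum() < min_pts:
            return np.inf, 1.0
        m = np.asarray(moving(zm[ok]), float)
        y = fixed_y[ok]
        denom = float(m @ m)
        if denom <= 0 or not np.isfinite(denom):
            return np.inf, 1.0
        scale = float(y @ m) / denom
        return float(np.mean((y - scale * m) ** 2)), scale

    step = z_increment / 4.0
    shifts = np.arange(-shift_halfwidth, shift_halfwidth + step / 2, step)
    costs = [cost(s)[0] for s in shifts]
    i = int(np.argmin(costs))
    if not np.isfinite(costs[i]):
        raise AlignmentError("no admissible shift: curves do not overlap")
    res = minimize_scalar(
        lambda s: cost(s)[0],
        bounds=(shifts[i] - step, shifts[i] + step),
        method="bounded",
        options={"xatol": z_increment / 1000.0},
    )
    shift = float(res.x) if np.isfinite(res.fun) and res.fun <= costs[i] else float(shifts[i])
    mse, scale = cost(shift)
    return shift, scale, float(np.sqrt(mse))


def _pick_reference(curves: list[SweepCurve], feature: str) -> SweepCurve:
    """Reference = curve with the most unsaturated points; ties to lowest exposure."""
    def rank(c: SweepCurve):
        n_unsat = int((~c.points[f"sat_{feature}"]).sum())
        return (-n_unsat, c.key[1], c.key[2])

    return sorted(curves, key=rank)[0]


def build_pooled_profile(
    curves: list[SweepCurve],
    feature: str,
    z_increment: float,
    reference_key: tuple | None = None,
) -> PooledProfile:
    """Align all curves to a reference and fit one spline to the pooled data.

    Each curve's own spline (fit to its unsaturated points) is aligned to
    the reference curve's unsaturated points; the curve's points are then
    mapped into the reference frame as (z + shift, y * scale) and a GCV
    smoothing spline is fit to the union.  Curves that fail to align are
    dropped with a warning.
    """
    import warnings

    if not curves:
        raise ValueError("no curves to pool")
    if reference_key is not None:
        ref = next(c for c in curves if c.key == reference_key)
    else:
        ref = _pick_reference(curves, feature)
    ref_z, ref_y = ref.feature_points(feature)
    if ref_z.size < 4:
        raise CurveError(f"reference curve {ref.key} has <4 unsaturated points")

    pooled_z, pooled_y = [], []
    alignments: dict = {}
    for curve in curves:
        z, y = curve.feature_points(feature)
        try:
            spline = _curve_spline(z, y)
            shift, scale, _ = align_curves(
                spline, (z.min(), z.max()), ref_z, ref_y, z_increment
            )
        except (CurveError, AlignmentError) as err:
            warnings.warn(f"dropping curve {curve.key} from {feature} pool: {err}")
            continue
        # scale*moving(z - shift) ~ fixed, so a moving point (u, y) lands
        # at (u + shift, y * scale) in the reference frame
        pooled_z.append(z + shift)
        pooled_y.append(y * scale)
        alignments[curve.key] = (shift, scale)
    if not pooled_z:
        raise AlignmentError(f"all curves failed {feature} pooling")
    zs = np.concatenate(pooled_z)
    ys = np.concatenate(pooled_y)
    order = np.argsort(zs, kind="stable")
    zs, ys = zs[order], ys[order]
    # GCV spline needs strictly increasing x: nudge-free dedup by averaging
    zu, inv, cnt = np.unique(np.round(zs, 9), return_inverse=True, return_counts=True)
    yu = np.zeros_like(zu)
    np.add.at(yu, inv, ys)
    yu /= cnt
    spline = make_smoothing_spline(zu, yu, w=cnt.astype(float))
    return PooledProfile(
        feature=feature, reference_key=ref.key, spline=spline,
        domain=(float(zu[0]), float(zu[-1])), alignments=alignments,
    )


def feature_refp(
    pooled: PooledProfile,
    curve: SweepCurve,
    z_increment: float,
) -> tuple[float, bool]:
    """Locate the feature-specific REFP for one curve.

    The pooled profile is fit (shift + scale) to the curve's unsaturated
    points, and the REFP is the Z of the fitted profile's extremum --
    minimum for SS, maximum for CI -- searched on a grid of z_increment/100
    over the sweep range.  Returns (refp_um, boundary_warning).
    """
    z, y = curve.feature_points(pooled.feature)
    if z.size < 4:
        raise AlignmentError(f"curve {curve.key}: <4 unsaturated points")
    shift, scale, _ = align_curves(pooled, pooled.domain, z, y, z_increment)
    z_all = curve.points["z_um"].to_numpy(float)
    lo = max(z_all.min(), pooled.domain[0] + shift)
    hi = min(z_all.max(), pooled.domain[1] + shift)
    grid = np.arange(lo, hi + z_increment / 200.0, z_increment / 100.0)
    vals = scale * pooled.spline(grid - shift)
    idx = int(np.argmin(vals)) if pooled.feature == "ss" else int(np.argmax(vals))
    refp = float(grid[idx])
    boundary = bool(refp <= lo + z_increment / 2 or refp >= hi - z_increment / 2)
    return refp, boundary


def compute_refp(refp_ss: float, refp_ci: float) -> float:
    """Final REFP: arithmetic mean of the two feature-specific REFPs."""
    if not (np.isfinite(refp_ss) and np.isfinite(refp_ci)):
        raise ValueError("feature REFPs must be finite")
    return (refp_ss + refp_ci) / 2.0


def infer_z_increment(features: pd.DataFrame) -> float:
    z = np.unique(features["z_um"].to_numpy(float))
    if z.size < 2:
        raise CurveError("cannot infer z increment from a single Z level")
    return float(np.median(np.diff(z)))


def estimate_refp(
    features: pd.DataFrame,
    z_increment: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full REFP estimation from a features table.

    Returns ``(refp_table, pooled)`` where the table has one row per
    (experiment, exposure_ms, fov) with refp_ss, refp_ci, refp_final and
    boundary_warning, and ``pooled`` maps feature name to its
    :class:`PooledProfile`.
    """
    if z_increment is None:
        z_increment = infer_z_increment(features)
    curves = [build_sweep_curve(g) for _, g in features.groupby(KEY, sort=True)]
    pooled = {
        feat: build_pooled_profile(curves, feat, z_increment) for feat in ("ss", "ci")
    }
    rows = []
    for curve in curves:
        r_ss, b_ss = feature_refp(pooled["ss"], curve, z_increment)
        r_ci, b_ci = feature_refp(pooled["ci"], curve, z_increment)
        rows.append(
            {"experiment": curve.key[0], "exposure_ms": curve.key[1],
             "fov": curve.key[2], "refp_ss": r_ss, "refp_ci": r_ci,
             "refp_final": compute_refp(r_ss, r_ci),
             "boundary_warning": b_ss or b_ci}
        )
    return pd.DataFrame(rows), pooled


def sweep_refp(refp_table: pd.DataFrame) -> float:
    """Sweep-level REFP: median of the per-curve final REFPs."""
    return float(refp_table["refp_final"].median())
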