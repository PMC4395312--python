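"""Serial-section alignment and normalization.

Pipeline, per animal:

1. ``rigid_align`` — register every section to the first one by the
   least-squares rigid transform (rotation + translation, no scaling)
   matching its four optical reference points.
2. ``normalize_sections`` — correct the cervical-enlargement diameter
   trend: per section, intersect a reference curve through five
   lateral-edge landmarks with the line through the central canal
   perpendicular to the mid-sagittal axis; spline-smooth the resulting
   intercept distances along the series; rescale each section
   isotropically about its canal so the smoothed profile is constant.
3. ``project_pool`` — project all neurons of one pool along the
   anterior-posterior axis into a single 2-D point set.

Scale correction is deliberately confined to step 2: using a rigid (not
similarity) registration in step 1 avoids correcting the diameter twice.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy.interpolate import CubicSpline, UnivariateSpline, interp1d
from scipy.optimize import brentq

from .errors import GeometryError
from .types import AlignedPool, SeriesTrace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

def fit_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (R, t) mapping src onto dst.

    Kabsch / orthogonal-Procrustes with the reflection excluded; returns
    (R, t, rms_residual) minimizing ||R src_i + t - dst_i||.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise GeometryError("fit_rigid needs matching (n, 2) point sets")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    resid = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return R, t, resid


def _check_reference_config(pts: np.ndarray, section_index: int) -> None:
    # coincident or collinear fiducials leave the rotation unconstrained
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    if np.max(d) < 1e-12:
        raise GeometryError(
            f"section {section_index}: optical reference points coincide"
        )
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * s[0]:
        raise GeometryError(
            f"section {section_index}: optical reference points are collinear"
        )


def rigid_align(series: SeriesTrace, template_index: int = 0) -> SeriesTrace:
    """Register every section onto a template section (default: the first).

    The rigid transform fitted on the 4 optical reference points is
    applied to neurons and all landmarks.  Per-section RMS residuals are
    stored in ``result.meta['alignment_residuals']``.
    """
    template = series.sections[template_index]
    _check_reference_config(template.optical_refs, template.section_index)
    aligned, residuals = [], []
    for sec in series.sections:
        _check_reference_config(sec.optical_refs, sec.section_index)
        R, t, resid = fit_rigid(sec.optical_refs, template.optical_refs)
        aligned.append(sec.transformed(R, t))
        residuals.append(resid)
    meta = dict(series.meta)
    meta["alignment_residuals"] = np.asarray(residuals)
    return replace(series, sections=aligned, meta=meta)


# ---------------------------------------------------------------------------
# reference curve and intercept
# ---------------------------------------------------------------------------

class ReferenceCurve:
    """Interpolating cubic spline through the 5 lateral-edge landmarks,
    parameterized by cumulative chord length."""

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, float)
        if pts.shape != (5, 2):
            raise GeometryError(f"reference curve needs exactly 5 points, got {pts.shape}")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise GeometryError("duplicate consecutive lateral-edge points")
        t = np.concatenate([[0.0], np.cumsum(seg)])
        self.t = t
        self.points = pts
        self._spline = CubicSpline(t, pts, axis=0)

    @property
    def t_max(self) -> float:
        return float(self.t[-1])

    def __call__(self, t):
        return self._spline(t)


def fit_reference_curve(lateral_edge: np.ndarray) -> ReferenceCurve:
    """Chord-length-parameterized cubic spline through the 5 edge points."""
    return ReferenceCurve(lateral_edge)


def intercept_point(
    curve: ReferenceCurve, central_canal, axis, tol: float = 1e-10
) -> np.ndarray:
    """Intersection of the reference curve with the perpendicular to the
    mid-sagittal axis through the central canal.

    If several intersections exist, the one on the lateral (positive
    perpendicular) side nearest the canal is returned.
    """
    c = np.asarray(central_canal, float).reshape(2)
    a = np.asarray(axis, float).reshape(2)
    a = a / np.linalg.norm(a)
    perp = np.array([a[1], -a[0]])  # lateral direction
    if perp[0] < 0:
        perp = -perp

    def h(t):
        # signed distance of curve(t) from the perpendicular line
        return float(np.dot(curve(t) - c, a))

    ts = np.linspace(0.0, curve.t_max, 512)
    hs = (curve(ts) - c) @ a
    roots = []
    for i in range(len(ts) - 1):
        if hs[i] == 0.0:
            roots.append(ts[i])
        elif hs[i] * hs[i + 1] < 0:
            roots.append(brentq(h, ts[i], ts[i + 1], xtol=tol))
    if hs[-1] == 0.0:
        roots.append(ts[-1])
    candidates = []
    for t in roots:
        p = curve(t)
        s = float(np.dot(p - c, perp))
        if s > 0:
            candidates.append((s, p))
    if not candidates:
        raise GeometryError(
            "perpendicular through the central canal does not intersect the "
            "reference curve on the lateral side"
        )
    return min(candidates, key=lambda sp: sp[0])[1]


def intercept_distance(section) -> float:
    """Canal-to-intercept distance of one section (hemicord radius proxy)."""
    curve = fit_reference_curve(section.lateral_edge)
    p = intercept_point(curve, section.central_canal, section.midsagittal_axis)
    return float(np.linalg.norm(p - section.central_canal))


# ---------------------------------------------------------------------------
# diameter normalization
# ---------------------------------------------------------------------------

def _smooth_profile(idx: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Spline-smooth intercept distances along the series.

    The smoothing factor is n * sigma^2 with sigma estimated from third
    differences (Var(diff^3) = 20 sigma^2 for white noise); third
    differences annihilate locally-quadratic trend, so a smooth
    enlargement profile is tracked nearly exactly while measurement noise
    and isolated outliers are damped.
    """
    n = len(d)
    if n < 4:
        logger.warning("only %d valid sections; falling back to linear interpolation", n)
        return interp1d(idx, d)(idx)
    dd = np.diff(d, 3)
    sigma2 = float(np.sum(dd**2) / (20 * len(dd))) if len(dd) else 0.0
    spl = UnivariateSpline(idx, d, k=3, s=n * sigma2)
    return spl(idx)


def normalize_sections(
    series: SeriesTrace,
    trend: str = "constant",
) -> SeriesTrace:
    """Rescale each section so the smoothed intercept-distance profile is flat.

    Per section i the canal-to-intercept distance d_i is measured, the
    profile d_i vs section index spline-smoothed to d_hat_i, and the
    section scaled isotropically about its canal by D / d_hat_i with
    D the mean smoothed distance.  This removes the cervical-enlargement
    diameter trend before pooling.

    ``trend='smoothed'`` applies the alternative reading — adjust each
    raw distance to its smoothed value (factor d_hat_i / d_i), which
    denoises but preserves the enlargement trend.  It is provided for
    comparison and is not the default because it does not correct the
    enlargement.

    Sections whose intercept cannot be computed are dropped with a
    warning.  Scale factors and dropped indices are recorded in
    ``result.meta``.
    """
    if trend not in ("constant", "smoothed"):
        raise ValueError("trend must be 'constant' or 'smoothed'")
    kept, idx, dists, dropped = [], [], [], []
    for sec in series.sections:
        try:
            d = intercept_distance(sec)
        except GeometryError as exc:
            logger.warning("section %d dropped: %s", sec.section_index, exc)
            dropped.append(sec.section_index)
            continue
        if d <= 0:
            raise GeometryError(
                f"section {sec.section_index}: non-positive intercept distance {d}"
            )
        kept.append(sec)
        idx.append(sec.section_index)
        dists.append(d)
    if len(kept) < 5:
        raise GeometryError(
            f"only {len(kept)} sections with a valid intercept; need >= 5"
        )
    idx = np.asarray(idx, float)
    dists = np.asarray(dists, float)
    d_hat = _smooth_profile(idx, dists)
    if np.any(d_hat <= 0):
        raise GeometryError("smoothed intercept-distance profile is non-positive")
    if trend == "constant":
        D = float(np.mean(d_hat))
        factors = D / d_hat
    else:
        factors = d_hat / dists
    scaled = [sec.scaled_about_canal(f) for sec, f in zip(kept, factors)]
    meta = dict(series.meta)
    meta["scale_factors"] = factors
    meta["intercept_distances"] = dists
    meta["smoothed_distances"] = d_hat
    meta["dropped_sections"] = dropped
    return replace(series, sections=scaled, meta=meta)


def project_pool(series: SeriesTrace, pool_label: str) -> AlignedPool:
    """Project all neurons of one pool along the anterior-posterior axis."""
    pts = series.pool_points(pool_label)
    return AlignedPool(
        pool_label=pool_label,
        points=pts,
        n_neurons=pts.shape[0],
        scale_factors=series.meta.get("scale_factors", np.ones(len(series.sections))),
    )


def align_and_project(series: SeriesTrace, pool_label: str) -> AlignedPool:
    """Convenience: rigid_align -> normalize_sections -> project_pool."""
    return project_pool(normalize_sections(rigid_align(series)), pool_label)
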