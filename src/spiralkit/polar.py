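"""Radius-angle ("unraveling") transform of a drawn spiral.

An ideal Archimedean spiral r = a + b*theta becomes a straight line when
re-expressed as radius versus unwrapped angle; deviation of a drawn spiral
from that line carries the shape information the irregularity indices
measure. This module produces the centered, direction-normalized polar
representation, resamples it onto a uniform angle grid, and linearly
detrends it into the residual series the indices consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import IndexConfig, DEFAULT_CONFIG
from .io import SpiralTrace

TWO_PI = 2.0 * np.pi


class DegenerateTraceError(ValueError):
    """Trace cannot be expressed in polar form (e.g. coincident with center)."""


@dataclass
class PolarTrace:
    """Unwrapped-angle representation of a spiral.

    theta is shifted to start at 0 and sign-normalized so that it is
    predominantly increasing regardless of the drawn rotation direction;
    ``direction`` records the direction as drawn ("CW" or "CCW").
    """

    theta: np.ndarray
    r: np.ndarray
    t: np.ndarray
    center: tuple[float, float]
    direction: str
    uniform: bool = False

    @property
    def revolutions(self) -> float:
        return float(self.theta[-1] - self.theta[0]) / TWO_PI

    @property
    def r_max(self) -> float:
        return float(np.max(self.r))


@dataclass
class ResidualSeries:
    """Residual radius after removing the best-fit line r = a + b*theta."""

    theta_grid: np.ndarray
    rho: np.ndarray
    slope: float
    intercept: float

    @property
    def grid_step(self) -> float:
        return float(self.theta_grid[1] - self.theta_grid[0])

    @property
    def revolutions(self) -> float:
        return float(self.theta_grid[-1] - self.theta_grid[0]) / TWO_PI


def estimate_center(trace: SpiralTrace, k: Optional[int] = None,
                    config: IndexConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Drawing-start center estimate: centroid of the first ``k`` samples.

    Subjects draw spirals from the center outward, so the first pen-down
    samples sit at the spiral origin.
    """
    k = config.center_k if k is None else int(k)
    if len(trace) < k:
        raise DegenerateTraceError(
            f"need at least {k} samples to estimate center, got {len(trace)}")
    return float(np.mean(trace.x[:k])), float(np.mean(trace.y[:k]))


def to_polar(trace: SpiralTrace, center: Optional[tuple[float, float]] = None,
             config: IndexConfig = DEFAULT_CONFIG) -> PolarTrace:
    """Unwrap a trace about its center into (theta, r, t).

    The unwrapped angle is shifted so theta[0] = 0 and sign-flipped if the
    net rotation is clockwise, making mirror-image spirals identical.
    """
    if center is None:
        center = estimate_center(trace, config=config)
    x0, y0 = center
    if not (np.isfinite(x0) and np.isfinite(y0)):
        raise DegenerateTraceError("non-finite center")
    dx = trace.x - x0
    dy = trace.y - y0
    r = np.hypot(dx, dy)
    # The angle of a sample inside the pen-rest jitter zone is meaningless
    # and corrupts the unwrap with spurious windings. Estimate the jitter
    # scale from the spread of the first K samples about their own centroid
    # (zero for a noise-free trace) and skip leading samples inside it.
    k = min(config.center_k, r.size)
    spread = float(np.sqrt(np.mean(
        (trace.x[:k] - np.mean(trace.x[:k])) ** 2
        + (trace.y[:k] - np.mean(trace.y[:k])) ** 2)))
    # cap the skip at a fraction of the drawing extent so extreme jitter
    # cannot swallow the whole spiral
    r_min = max(min(6.0 * spread, 0.3 * float(np.max(r))), 1e-12)
    above = np.nonzero(r >= r_min)[0]
    if above.size == 0:
        raise DegenerateTraceError("all samples coincide with the center")
    start = int(above[0])
    # zero-radius samples (pen resting at the center) have no defined angle
    nz = np.zeros(r.size, dtype=bool)
    nz[start:] = r[start:] > 1e-12
    dx, dy, r = dx[nz], dy[nz], r[nz]
    t = trace.t.astype(float)[nz]
    theta = np.unwrap(np.arctan2(dy, dx))
    net = theta[-1] - theta[0]
    if net == 0:
        raise DegenerateTraceError("no net rotation about the center")
    direction = "CCW" if net > 0 else "CW"
    if net < 0:
        theta = -theta
    theta = theta - theta[0]
    return PolarTrace(theta=theta, r=r, t=t,
                      center=(x0, y0), direction=direction)


def _strictly_increasing_view(polar: PolarTrace,
                              backtrack_tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop backtracking samples so theta is strictly increasing.

    Hand jitter near the center makes the unwrapped angle retreat briefly;
    samples more than ``backtrack_tol`` radians behind the running maximum
    are removed, then residual non-increasing samples are dropped.
    """
    theta, r, t = polar.theta, polar.r, polar.t
    running = np.maximum.accumulate(theta)
    keep = theta >= running - backtrack_tol
    theta, r, t = theta[keep], r[keep], t[keep]
    # enforce strict monotonicity for interpolation
    keep2 = np.ones(theta.size, dtype=bool)
    last = -np.inf
    for i, th in enumerate(theta):
        if th > last:
            last = th
        else:
            keep2[i] = False
    return theta[keep2], r[keep2], t[keep2]


def resample_uniform(polar: PolarTrace, bins_per_rev: Optional[int] = None,
                     config: IndexConfig = DEFAULT_CONFIG) -> PolarTrace:
    """Interpolate (r, t) onto a uniform angle grid.

    The grid has spacing 2*pi/bins_per_rev starting at theta = 0; the last
    grid point is the largest multiple of the spacing not exceeding the
    trace's maximal angle, so resampling is idempotent.

    The radius is interpolated with a shape-preserving cubic (PCHIP): pen
    samples are sparser in angle than the grid (especially for fast or wide
    spirals), and a piecewise-linear interpolant would leave slope kinks at
    every sample whose size depends on the drawing speed, biasing the
    curvature-based smoothness index by sampling density rather than by
    drawn shape; an ordinary spline, conversely, rings where the angular
    sample spacing is very uneven near the center. Samples closer in angle
    than half a grid step are thinned first. Time, used only for ordering
    and filtering, is interpolated linearly.
    """
    bins = config.bins_per_rev if bins_per_rev is None else int(bins_per_rev)
    theta, r, t = _strictly_increasing_view(polar, config.backtrack_tol)
    if theta.size < 2:
        raise DegenerateTraceError("too few monotone samples to resample")
    span = theta[-1] - theta[0]
    if span < TWO_PI:
        raise DegenerateTraceError(
            f"spiral spans {span / TWO_PI:.2f} revolutions; need at least 1")
    h = TWO_PI / bins
    # thin samples the grid cannot resolve (keep first of each cluster and
    # always the final sample, so the endpoint survives)
    keep = np.empty(theta.size, dtype=bool)
    keep[0] = True
    last = theta[0]
    for i in range(1, theta.size):
        keep[i] = (theta[i] - last) >= 0.5 * h
        if keep[i]:
            last = theta[i]
    keep[-1] = True
    if keep.size >= 2 and theta[-1] - theta[np.flatnonzero(keep)[-2]] < 1e-12:
        keep[np.flatnonzero(keep)[-2]] = False
    theta, r, t = theta[keep], r[keep], t[keep]
    span = theta[-1] - theta[0]
    # tolerate float fuzz so an exact-multiple span keeps its endpoint
    n = int(np.floor(span / h + 1e-9)) + 1
    grid = theta[0] + h * np.arange(n)
    if theta.size >= 4:
        from scipy.interpolate import PchipInterpolator
        r_g = PchipInterpolator(theta, r)(grid)
    else:
        r_g = np.interp(grid, theta, r)
    t_g = np.interp(grid, theta, t)
    return PolarTrace(theta=grid - grid[0], r=r_g, t=t_g, center=polar.center,
                      direction=polar.direction, uniform=True)


def detrend_linear(polar: PolarTrace) -> ResidualSeries:
    """Ordinary least-squares line fit r = intercept + slope*theta.

    The residual rho = r - fit is the series all shape indices are defined
    on; for an ideal outward spiral the slope is the loop spacing per radian
    and rho vanishes.
    """
    theta, r = polar.theta, polar.r
    if theta[-1] - theta[0] < TWO_PI:
        raise DegenerateTraceError("need at least one revolution to detrend")
    if np.ptp(theta) == 0:
        raise DegenerateTraceError("constant angle: singular fit")
    slope, intercept = np.polyfit(theta, r, 1)
    rho = r - (intercept + slope * theta)
    return ResidualSeries(theta_grid=theta, rho=rho,
                          slope=float(slope), intercept=float(intercept))


def polar_pipeline(trace: SpiralTrace,
                   config: IndexConfig = DEFAULT_CONFIG
                   ) -> tuple[PolarTrace, PolarTrace, ResidualSeries]:
    """Center, unwrap, resample and detrend one trace.

    Returns the raw polar trace, the uniform-grid polar trace, and the
    detrended residual series (computed once and shared by the indices).
    """
    stroke = trace.longest_stroke()
    polar = to_polar(stroke, config=config)
    uniform = resample_uniform(polar, config=config)
    res = detrend_linear(uniform)
    return polar, uniform, res
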