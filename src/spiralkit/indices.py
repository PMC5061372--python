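"""The six per-spiral indices and per-subject aggregation.

Indices
-------
DoS
    Degree of severity: composite 0-4 score of overall spiral execution,
    mirroring the five-point clinical rating of handwritten spirals
    (0-1 normal, 1-2 mild, 2-3 moderate, 3-4 severely abnormal).
2ndSm
    Second-order smoothness: log of the mean squared second difference
    (w.r.t. angle) of the detrended radius residual; curvature irregularity
    of the unraveled spiral.
1stZC
    First-order zero-crossing rate: how often the first difference of the
    residual changes sign, per revolution; sensitive to small frequent
    fluctuations.
T
    Tightness, loops/cm: number of turns divided by the maximal radius;
    the computational correlate of micrographia.
mSp
    Mean drawing speed, cm/s: total path length over total drawing time.
SWVI
    Spiral-width variability index: coefficient of variation of the
    per-angle median loop-to-loop widths, computed after low-pass removal
    of tremor oscillation; a correlate of ataxic/erratic drawing.

Hand asymmetry is summarized per subject as the absolute difference of
each aggregated index between the dominant and non-dominant hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Optional

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.special import expit

from .config import IndexConfig, DosWeights, DEFAULT_CONFIG
from .io import SpiralTrace, SubjectMeta, HANDS
from .polar import (PolarTrace, ResidualSeries, DegenerateTraceError,
                    polar_pipeline, resample_uniform, TWO_PI)

#: canonical column order of the index table
INDEX_NAMES = ("DoS", "SecondSm", "FirstZC", "T", "mSp", "SWVI")

#: numerical floor of the log in 2ndSm, for numerically perfect spirals
SMOOTHNESS_EPS = 1e-12

#: residual magnitudes below this (cm) are treated as exact zeros when
#: counting sign changes, so float round-off cannot register crossings
ZC_EPS = 1e-9


class IndexComputationError(ValueError):
    pass


@dataclass(frozen=True)
class IndexSet:
    DoS: float
    SecondSm: float
    FirstZC: float
    T: float
    mSp: float
    SWVI: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> "IndexSet":
        d = self.as_dict()
        if not all(math.isfinite(v) for v in d.values()):
            raise IndexComputationError(f"non-finite index in {d}")
        if not (0.0 <= self.DoS <= 4.0):
            raise IndexComputationError(f"DoS {self.DoS} outside [0, 4]")
        if self.T <= 0 or self.mSp <= 0 or self.SWVI < 0:
            raise IndexComputationError(f"index out of range in {d}")
        return self


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates plus per-hand aggregated indices and hand differences."""

    meta: SubjectMeta
    dom: IndexSet
    nondom: IndexSet
    diff: IndexSet


def mean_speed(trace: SpiralTrace) -> float:
    """Mean drawing speed in cm/s.

    Average consecutive segment length over average inter-sample time,
    which equals total path length divided by total elapsed time.
    """
    if len(trace) < 2:
        raise IndexComputationError("need at least 2 samples for speed")
    elapsed = float(trace.t[-1] - trace.t[0])
    if elapsed <= 0:
        raise IndexComputationError("zero elapsed time")
    path = float(np.sum(np.hypot(np.diff(trace.x), np.diff(trace.y))))
    return path / elapsed


def tightness(polar: PolarTrace) -> float:
    """Loops per cm: turns drawn over the maximal radius.

    Spirals are drawn from the center outward, but the innermost sliver of
    angle is unresolvable (pen-rest jitter) and may have been skipped by the
    polar transform. The angular span is therefore extended to the point
    where the least-squares line r = a + b*theta reaches r = 0, recovering
    the drawn turns; the correction is capped at half a revolution.
    """
    span = polar.theta[-1] - polar.theta[0]
    if span < TWO_PI:
        raise IndexComputationError("tightness undefined below one revolution")
    r_max = polar.r_max
    if r_max <= 0:
        raise IndexComputationError("zero maximal radius")
    slope, intercept = np.polyfit(polar.theta, polar.r, 1)
    if slope > 1e-6 and intercept > 0:
        span += min(intercept / slope, np.pi)
    return float(span / TWO_PI / r_max)


def second_order_smoothness(res: ResidualSeries) -> float:
    """ln of the mean squared second difference of rho w.r.t. theta."""
    if res.revolutions < 2:
        raise IndexComputationError("2ndSm requires at least two revolutions")
    h = res.grid_step
    d2 = (res.rho[2:] - 2.0 * res.rho[1:-1] + res.rho[:-2]) / (h * h)
    msq = float(np.mean(d2 * d2))
    return float(np.log(max(msq, SMOOTHNESS_EPS)))


def first_order_zero_crossings(res: ResidualSeries,
                               config: IndexConfig = DEFAULT_CONFIG) -> float:
    """Sign changes of the first difference of rho, per revolution.

    A zero sample inherits the preceding sign, so a touch-and-go at zero
    counts once. ``config.zc_on_residual`` counts crossings of rho itself;
    ``config.zc_per_revolution=False`` returns the raw count.
    """
    if res.revolutions < 2:
        raise IndexComputationError("1stZC requires at least two revolutions")
    series = res.rho if config.zc_on_residual else np.diff(res.rho)
    s = np.sign(np.where(np.abs(series) <= ZC_EPS, 0.0, series))
    # zeros attach to the preceding sign
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    s = s[s != 0]
    crossings = int(np.count_nonzero(s[1:] != s[:-1]))
    if not config.zc_per_revolution:
        return float(crossings)
    return crossings / res.revolutions


def _lowpass_radius(polar: PolarTrace, cutoff_hz: float) -> PolarTrace:
    """Zero-phase low-pass of the radius in the time domain.

    The linear radius-vs-angle trend is removed first (near the spiral
    center the radius sweeps quickly through time, so filtering the raw
    radius would distort the innermost loop), the residual is interpolated
    onto a uniform time grid at the trace's median sampling rate, filtered
    forward-backward (4th-order Butterworth), and the trend restored.
    """
    t, r, theta = polar.t, polar.r, polar.theta
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise IndexComputationError("non-increasing time in polar trace")
    fs = 1.0 / dt
    if cutoff_hz <= 0 or cutoff_hz >= fs / 2:
        return polar  # nothing to remove at/above Nyquist
    slope, intercept = np.polyfit(theta, r, 1)
    trend = intercept + slope * theta
    tg = np.arange(t[0], t[-1] + dt / 2, dt)
    rg = np.interp(tg, t, r - trend)
    b, a = butter(4, cutoff_hz / (fs / 2), btype="low")
    padlen = min(3 * (max(len(a), len(b)) - 1), rg.size - 1)
    rf = filtfilt(b, a, rg, padlen=padlen)
    r_s = np.interp(t, tg, rf) + trend
    return PolarTrace(theta=polar.theta, r=r_s, t=t, center=polar.center,
                      direction=polar.direction, uniform=polar.uniform)


def spiral_width_variability(res: ResidualSeries, polar: PolarTrace,
                             config: IndexConfig = DEFAULT_CONFIG) -> float:
    """CV of per-angle median loop-to-loop spiral widths, tremor removed.

    Steps: (1) low-pass the radius in the time domain (default 2 Hz cutoff,
    below the 4-6 Hz tremor band); (2) resample onto the uniform angle grid
    and, for each of the ``bins_per_rev`` angles, collect the widths between
    successive loops at that angle; (3) take the per-angle median width;
    (4) return sd/mean of those medians.

    The ``polar`` argument is the trace in its raw polar form (so the time
    axis is available for filtering); ``res`` supplies the angle-grid
    resolution.
    """
    bins = int(round(TWO_PI / res.grid_step))
    smooth = _lowpass_radius(polar, config.tremor_cutoff_hz)
    grid = resample_uniform(smooth, bins_per_rev=bins, config=config)
    n_loops = grid.r.size // bins  # complete loops on the grid
    if n_loops < 2:
        raise IndexComputationError("SWVI requires at least two full loops")
    r_loops = grid.r[: n_loops * bins].reshape(n_loops, bins)
    widths = np.diff(r_loops, axis=0)            # (n_loops-1, bins)
    medians = np.median(widths, axis=0)          # per-angle median width
    mean_w = float(np.mean(medians))
    if mean_w <= 0:
        raise IndexComputationError("non-positive mean spiral width")
    return float(np.std(medians) / mean_w)


def degree_of_severity(res: ResidualSeries, polar: PolarTrace,
                       trace: SpiralTrace,
                       weights: Optional[DosWeights] = None,
                       config: IndexConfig = DEFAULT_CONFIG) -> float:
    """Composite 0-4 severity score of overall spiral execution.

    DoS = 4 * logistic(w0 + w_rms * RMS(rho)/r_max + w_sm * 2ndSm
                          + w_cv * CV(speed)),
    monotone non-decreasing in each irregularity component. The weights are
    a documented calibration living in config (see :class:`DosWeights`).
    """
    w = weights if weights is not None else config.dos_weights
    if w is None:
        raise IndexComputationError("DoS weights missing from config")
    r_max = polar.r_max
    if r_max <= 0:
        raise IndexComputationError("zero maximal radius")
    z_rms = float(np.sqrt(np.mean(res.rho ** 2))) / r_max
    z_sm = second_order_smoothness(res)
    seg = np.hypot(np.diff(trace.x), np.diff(trace.y))
    dt = np.diff(trace.t)
    speeds = seg / dt
    mean_v = float(np.mean(speeds))
    if mean_v <= 0:
        raise IndexComputationError("zero mean speed")
    z_cv = float(np.std(speeds)) / mean_v
    score = w.w0 + w.w_rms * z_rms + w.w_sm * z_sm + w.w_cv * z_cv
    return float(4.0 * expit(score))


def compute_index_set(trace: SpiralTrace,
                      config: IndexConfig = DEFAULT_CONFIG) -> IndexSet:
    """All six indices for one spiral trace (deterministic given config)."""
    try:
        polar, uniform, res = polar_pipeline(trace, config=config)
        return IndexSet(
            DoS=degree_of_severity(res, uniform, trace, config=config),
            SecondSm=second_order_smoothness(res),
            FirstZC=first_order_zero_crossings(res, config=config),
            T=tightness(uniform),
            mSp=mean_speed(trace),
            SWVI=spiral_width_variability(res, polar, config=config),
        ).validate()
    except (DegenerateTraceError, IndexComputationError) as exc:
        raise IndexComputationError(
            f"{trace.subject_id} hand={trace.hand} trial={trace.trial}: {exc}"
        ) from exc


def aggregate_hand(index_sets: list[IndexSet]) -> IndexSet:
    """Aggregate trials of one hand: mean per index, median for SWVI."""
    if not index_sets:
        raise IndexComputationError("no trials to aggregate")
    cols = {name: np.array([getattr(s, name) for s in index_sets])
            for name in INDEX_NAMES}
    agg = {name: float(np.mean(v)) for name, v in cols.items()}
    agg["SWVI"] = float(np.median(cols["SWVI"]))
    return IndexSet(**agg)


def aggregate_subject(meta: SubjectMeta,
                      index_sets: Mapping[tuple[str, int], IndexSet]
                      ) -> SubjectRecord:
    """Per-subject record: per-hand aggregates and |dominant - non-dominant|."""
    by_hand: dict[str, list[IndexSet]] = {h: [] for h in HANDS}
    for (hand, _trial), s in sorted(index_sets.items()):
        if hand not in by_hand:
            raise IndexComputationError(f"{meta.subject_id}: unknown hand {hand!r}")
        by_hand[hand].append(s)
    for hand in HANDS:
        if not by_hand[hand]:
            raise IndexComputationError(f"{meta.subject_id}: no {hand}-hand trials")
    dom = aggregate_hand(by_hand["dominant"])
    nondom = aggregate_hand(by_hand["nondominant"])
    diff = IndexSet(**{n: abs(getattr(dom, n) - getattr(nondom, n))
                       for n in INDEX_NAMES})
    return SubjectRecord(meta=meta, dom=dom, nondom=nondom, diff=diff)
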