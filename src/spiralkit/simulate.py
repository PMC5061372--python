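"""Generative model of spiral-drawing kinematics with known ground truth.

The generator emulates the acquisition protocol the indices were designed
for: Archimedean spirals drawn from the center outward inside a 10x10 cm
square, sampled at ~100 Hz, ten trials per hand per subject. A drawn spiral
is modeled as an ideal Archimedean trajectory traversed at constant
tangential speed, perturbed by three independent noise processes:

* a smooth random radial irregularity field along the unwound angle
  (Gaussian knots at a fixed angular coherence scale, cubic-spline
  interpolated; amplitude ``irregularity_sd``) giving trajectory roughness
  whose per-revolution structure is intrinsic to the drawn shape, not to
  the drawing speed (drives 2ndSm, 1stZC, DoS);
* a sinusoidal radial tremor oscillation (``tremor_amp`` at ``tremor_freq``,
  typically in the 4-6 Hz parkinsonian action-tremor band);
* a slow sinusoidal loop-spacing drift (``width_drift_amp``) modulating the
  spacing between successive loops (drives SWVI).

Group presets encode the qualitative impairment pattern of parkinsonian
drawing relative to controls — slower, tighter, more irregular, more
asymmetric between hands — with parameter levels documented in
``docs/methods.md``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline

from .io import (SpiralTrace, SubjectMeta, write_traces, write_cohort_meta)

RngLike = Union[int, np.random.Generator]

#: drawings must fit a 10x10 cm square, i.e. maximal radius of 5 cm
MAX_RADIUS_CM = 5.0

#: angular coherence scale (rad) of the radial irregularity field; sets the
#: intrinsic roughness wavelength of a drawn loop (~9 wiggles/revolution)
IRREGULARITY_SCALE_RAD = 0.7

#: loop-spacing drift is capped at this fraction of the loop spacing so
#: successive loops cannot cross (which would make spiral widths negative)
MAX_DRIFT_FRACTION = 0.60


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DrawingParams:
    """Subject/trial-level parameters of one simulated spiral."""

    loop_spacing: float = 0.9      # cm per turn
    n_turns: float = 5.0
    base_speed: float = 20.0       # cm/s tangential
    tremor_amp: float = 0.0        # cm
    tremor_freq: float = 5.0       # Hz
    irregularity_sd: float = 0.0   # cm, stationary sd of the radial walk
    width_drift_amp: float = 0.0   # cm, slow loop-spacing modulation
    sample_rate: float = 100.0     # Hz
    hand_asymmetry: float = 1.0    # impairment multiplier for the worse hand
    dwell_s: float = 0.05          # pen resting at the center before drawing
    ramp_s: float = 0.25           # acceleration ramp to cruise speed

    def validate(self) -> "DrawingParams":
        vals = asdict(self)
        if any(v < 0 for v in vals.values()):
            raise ValueError(f"negative drawing parameter in {vals}")
        if self.loop_spacing * self.n_turns > MAX_RADIUS_CM:
            raise ValueError(
                f"spiral radius {self.loop_spacing * self.n_turns:.2f} cm "
                f"exceeds the {MAX_RADIUS_CM:.0f} cm half-square")
        if self.sample_rate <= 0 or self.base_speed <= 0 or self.n_turns <= 0:
            raise ValueError("sample_rate, base_speed and n_turns must be positive")
        return self

    def scaled(self, factor: float) -> "DrawingParams":
        """Multiply the impairment parameters (tremor, irregularity, drift)
        and divide the speed by ``factor``; used for hand asymmetry."""
        spacing = self.loop_spacing / (1.0 + 0.3 * (factor - 1.0))
        return DrawingParams(
            loop_spacing=spacing,
            n_turns=self.n_turns,
            base_speed=self.base_speed,
            tremor_amp=self.tremor_amp * factor,
            tremor_freq=self.tremor_freq,
            irregularity_sd=self.irregularity_sd * factor,
            width_drift_amp=min(self.width_drift_amp * factor,
                                MAX_DRIFT_FRACTION * spacing),
            sample_rate=self.sample_rate,
            hand_asymmetry=1.0,
        )


#: maximal-degradation preset used to anchor the top of the DoS scale
MAX_DEGRADATION = DrawingParams(
    loop_spacing=0.55, n_turns=5.0, base_speed=5.0,
    tremor_amp=0.12, tremor_freq=5.0,
    irregularity_sd=0.10, width_drift_amp=0.60,
)


def _arc_length(b: float, theta: float) -> float:
    """Arc length of the Archimedean spiral r = b*theta from 0 to theta."""
    return 0.5 * b * (theta * math.sqrt(1.0 + theta * theta)
                      + math.asinh(theta))


def simulate_trace(params: DrawingParams, seed: RngLike,
                   subject_id: str = "sim", hand: str = "dominant",
                   trial: int = 1,
                   center: tuple[float, float] = (5.0, 5.0)) -> SpiralTrace:
    """Simulate one drawn spiral; deterministic given params and seed.

    The pen rests at the center for ``dwell_s``, accelerates quadratically
    over ``ramp_s``, then cruises at constant tangential speed; the cruise
    speed is set analytically so that total path length over total time
    equals ``base_speed`` exactly (the ground truth for the mean-speed
    index). The angle trajectory integrates
    d(theta)/dt = v(t) / |ds/dtheta| for the ideal spiral r = b*theta/2pi;
    the noise processes then perturb the radius before conversion to (x, y).
    """
    params.validate()
    rng = _rng(seed)
    b = params.loop_spacing / (2.0 * math.pi)  # cm per radian
    dt = 1.0 / params.sample_rate
    theta_end = 2.0 * math.pi * params.n_turns

    # cruise speed compensating the dwell/ramp overhead: the quadratic ramp
    # covers v_c*ramp/3 of path in ramp_s seconds
    length = _arc_length(b, theta_end)
    denom = length / params.base_speed - params.dwell_s - 2.0 / 3.0 * params.ramp_s
    v_cruise = length / denom if denom > 0 else params.base_speed

    n_dwell = int(round(params.dwell_s * params.sample_rate))
    thetas = [0.0]
    th = 0.0
    elapsed = 0.0
    # generous cap so pathological parameters cannot loop forever
    max_steps = int(5e6)
    while th < theta_end and len(thetas) < max_steps:
        v = v_cruise if elapsed >= params.ramp_s else \
            v_cruise * (elapsed / params.ramp_s) ** 2
        th = min(th + dt * v / math.hypot(b * th, b), theta_end)
        elapsed += dt
        thetas.append(th)
    theta = np.concatenate([np.zeros(n_dwell), np.asarray(thetas)])
    n = theta.size
    t = dt * np.arange(n)

    r = b * theta
    if params.irregularity_sd > 0:
        delta = IRREGULARITY_SCALE_RAD
        knots = np.arange(-delta, theta_end + 2.0 * delta, delta)
        vals = rng.normal(0.0, params.irregularity_sd, knots.size)
        r = r + CubicSpline(knots, vals)(theta)
    if params.tremor_amp > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r = r + params.tremor_amp * np.sin(
            2.0 * math.pi * params.tremor_freq * t + phase)
    if params.width_drift_amp > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        r = r + params.width_drift_amp * np.sin(theta / 2.0 + phase)
    r = np.clip(r, 0.0, None)

    x = center[0] + r * np.cos(theta)
    y = center[1] + r * np.sin(theta)
    if n_dwell > 0:
        # pen resting at the center jitters isotropically, not radially
        jitter_sd = math.hypot(params.irregularity_sd,
                               params.tremor_amp / math.sqrt(2.0))
        x[:n_dwell] = center[0] + jitter_sd * rng.standard_normal(n_dwell)
        y[:n_dwell] = center[1] + jitter_sd * rng.standard_normal(n_dwell)
    p = np.clip(128.0 + 3.0 * rng.standard_normal(n), 0.0, 255.0)
    return SpiralTrace(subject_id, hand, trial, t, x, y, p).validate()


@dataclass(frozen=True)
class ParamDist:
    """Truncated normal distribution for one drawing parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(1000):
            v = rng.normal(self.mean, self.sd)
            if self.lo <= v <= self.hi:
                return float(v)
        return float(np.clip(self.mean, self.lo, self.hi))


@dataclass(frozen=True)
class GroupPreset:
    """Population distributions of drawing parameters and covariates."""

    name: str
    loop_spacing: ParamDist
    n_turns: ParamDist
    base_speed: ParamDist
    tremor_amp: ParamDist
    tremor_freq: ParamDist
    irregularity_sd: ParamDist
    width_drift_amp: ParamDist
    hand_asymmetry: ParamDist
    age: ParamDist
    p_female: float
    p_right_handed: float = 0.86
    sample_rate: float = 100.0
    #: multiplicative sd of trial-to-trial lognormal jitter
    trial_jitter: float = 0.06

    def draw_params(self, rng: np.random.Generator) -> DrawingParams:
        spacing = self.loop_spacing.draw(rng)
        return DrawingParams(
            loop_spacing=spacing,
            n_turns=self.n_turns.draw(rng),
            base_speed=self.base_speed.draw(rng),
            tremor_amp=self.tremor_amp.draw(rng),
            tremor_freq=self.tremor_freq.draw(rng),
            irregularity_sd=self.irregularity_sd.draw(rng),
            width_drift_amp=min(self.width_drift_amp.draw(rng),
                                MAX_DRIFT_FRACTION * spacing),
            sample_rate=self.sample_rate,
            hand_asymmetry=self.hand_asymmetry.draw(rng),
        )


# Default presets. Levels follow the impairment pattern of parkinsonian
# graphomotor control: lower drawing speed, tighter loops (micrographia),
# action tremor in the 4-6 Hz band, rougher trajectories, larger loop-width
# drift, and stronger between-hand asymmetry. The zero-crossing rate is
# deliberately kept near-equal between groups (broad-band roughness levels
# overlap), matching its behavior as a non-discriminating index.
CONTROL_PRESET = GroupPreset(
    name="control",
    loop_spacing=ParamDist(0.92, 0.16, 0.60, 1.00),
    n_turns=ParamDist(5.0, 0.0, 5.0, 5.0),
    base_speed=ParamDist(21.5, 7.5, 8.0, 42.0),
    tremor_amp=ParamDist(0.005, 0.004, 0.0, 0.015),
    tremor_freq=ParamDist(5.0, 0.7, 3.5, 6.5),
    irregularity_sd=ParamDist(0.022, 0.007, 0.006, 0.045),
    width_drift_amp=ParamDist(0.28, 0.10, 0.05, 0.60),
    hand_asymmetry=ParamDist(1.15, 0.12, 1.0, 1.60),
    age=ParamDist(64.25, 14.26, 40.0, 94.0),
    p_female=0.607,
)

PD_PRESET = GroupPreset(
    name="PD",
    loop_spacing=ParamDist(0.78, 0.20, 0.42, 1.00),
    n_turns=ParamDist(5.0, 0.0, 5.0, 5.0),
    base_speed=ParamDist(19.0, 9.0, 4.0, 40.0),
    tremor_amp=ParamDist(0.005, 0.004, 0.0, 0.015),
    tremor_freq=ParamDist(5.0, 0.7, 3.5, 6.5),
    irregularity_sd=ParamDist(0.024, 0.009, 0.008, 0.055),
    width_drift_amp=ParamDist(0.33, 0.12, 0.05, 0.70),
    hand_asymmetry=ParamDist(1.32, 0.20, 1.0, 2.0),
    age=ParamDist(65.12, 10.40, 34.0, 88.0),
    p_female=0.457,
)

DEFAULT_PRESETS = {"control": CONTROL_PRESET, "PD": PD_PRESET}

#: disease-duration model for simulated PD subjects (years)
EARLY_DURATION = ParamDist(3.0, 1.4, 0.3, 5.0)
LATE_DURATION = ParamDist(9.5, 3.5, 5.1, 25.0)


def _jitter(params: DrawingParams, sigma: float,
            rng: np.random.Generator) -> DrawingParams:
    """Trial-level lognormal jitter of speed, spacing and noise amplitudes."""
    g = lambda: float(np.exp(rng.normal(0.0, sigma)))
    spacing = min(params.loop_spacing * g(), MAX_RADIUS_CM / params.n_turns)
    return DrawingParams(
        loop_spacing=spacing,
        n_turns=params.n_turns,
        base_speed=params.base_speed * g(),
        tremor_amp=params.tremor_amp * g(),
        tremor_freq=params.tremor_freq,
        irregularity_sd=params.irregularity_sd * g(),
        width_drift_amp=min(params.width_drift_amp * g(),
                            MAX_DRIFT_FRACTION * spacing),
        sample_rate=params.sample_rate,
        hand_asymmetry=params.hand_asymmetry,
    )


def simulate_subject(preset: GroupPreset, subject_id: str, seed: RngLike,
                     trials_per_hand: int = 10,
                     duration: Optional[float] = None
                     ) -> tuple[SubjectMeta, list[SpiralTrace], dict]:
    """Simulate one subject: metadata plus 10 traces per hand.

    The subject's base drawing parameters are drawn from the preset; the
    ``hand_asymmetry`` multiplier degrades one hand (the side is random, as
    parkinsonian onset is). Each trial adds lognormal jitter. Returns the
    metadata, the traces, and a ground-truth parameter dict.
    """
    rng = _rng(seed)
    base = preset.draw_params(rng)
    meta = SubjectMeta(
        subject_id=subject_id,
        group="PD" if preset.name == "PD" else "control",
        age=preset.age.draw(rng),
        sex="F" if rng.random() < preset.p_female else "M",
        handedness="right" if rng.random() < preset.p_right_handed else "left",
        disease_duration=duration if preset.name == "PD" else None,
    ).validate()
    worse_hand = "dominant" if rng.random() < 0.5 else "nondominant"
    traces: list[SpiralTrace] = []
    for hand in ("dominant", "nondominant"):
        hand_params = (base.scaled(base.hand_asymmetry)
                       if hand == worse_hand else base)
        for trial in range(1, trials_per_hand + 1):
            tp = _jitter(hand_params, preset.trial_jitter, rng)
            traces.append(simulate_trace(tp, rng, subject_id=subject_id,
                                         hand=hand, trial=trial))
    truth = {"subject_id": subject_id, "group": meta.group,
             "worse_hand": worse_hand, **asdict(base)}
    return meta, traces, truth


def generate_cohort(n_pd: int = 138, n_control: int = 150,
                    n_early_pd: int = 50, seed: RngLike = 0,
                    trials_per_hand: int = 10,
                    presets: Optional[dict[str, GroupPreset]] = None
                    ) -> tuple[list[SubjectMeta], list[SpiralTrace], list[dict]]:
    """Simulate a full case-control cohort in memory.

    Exactly ``n_early_pd`` of the PD subjects receive a disease duration of
    at most 5 years ("early PD"); the remainder are drawn above 5 years.
    """
    if n_early_pd > n_pd:
        raise ValueError("n_early_pd cannot exceed n_pd")
    presets = presets or DEFAULT_PRESETS
    rng = _rng(seed)
    metas: list[SubjectMeta] = []
    traces: list[SpiralTrace] = []
    truths: list[dict] = []
    for i in range(n_pd):
        dur_dist = EARLY_DURATION if i < n_early_pd else LATE_DURATION
        duration = dur_dist.draw(rng)
        m, tr, gt = simulate_subject(presets["PD"], f"PD{i + 1:03d}", rng,
                                     trials_per_hand, duration=duration)
        metas.append(m); traces.extend(tr); truths.append(gt)
    for i in range(n_control):
        m, tr, gt = simulate_subject(presets["control"], f"C{i + 1:03d}", rng,
                                     trials_per_hand)
        metas.append(m); traces.extend(tr); truths.append(gt)
    return metas, traces, truths


def simulate_cohort(out_dir, n_pd: int = 138, n_control: int = 150,
                    n_early_pd: int = 50, seed: RngLike = 0,
                    trials_per_hand: int = 10,
                    presets: Optional[dict[str, GroupPreset]] = None) -> dict:
    """Simulate a cohort and write it to disk.

    Writes ``cohort.csv`` (metadata), per-subject trace CSVs under
    ``traces/``, and ``ground_truth.json``. Returns a manifest dict.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    metas, traces, truths = generate_cohort(
        n_pd, n_control, n_early_pd, seed, trials_per_hand, presets)
    write_cohort_meta(metas, out / "cohort.csv")
    by_subject: dict[str, list[SpiralTrace]] = {}
    for tr in traces:
        by_subject.setdefault(tr.subject_id, []).append(tr)
    trace_files = {}
    for sid, trs in by_subject.items():
        path = out / "traces" / f"{sid}.csv"
        write_traces(trs, path)
        trace_files[sid] = str(path)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)
    manifest = {"cohort": str(out / "cohort.csv"), "traces": trace_files,
                "ground_truth": str(out / "ground_truth.json"),
                "n_pd": n_pd, "n_control": n_control,
                "n_early_pd": n_early_pd,
                "seed": seed if isinstance(seed, int) else None}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
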