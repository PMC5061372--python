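"""Analysis configuration: every tunable knob of the index pipeline in one place.

Defaults are chosen for spirals drawn inside a 10x10 cm square and sampled
at ~100 Hz. The degree-of-severity composite weights are a documented,
configurable calibration: they map the 0-4 clinical spiral rating scale onto
three normalized irregularity components and are set so that a noise-free
Archimedean spiral scores below 1 ("normal") and a maximally degraded
simulated spiral scores above 3 ("severely abnormal").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class DosWeights:
    """Logistic weights of the 0-4 degree-of-severity composite.

    DoS = 4 * logistic(w0 + w_rms * RMS(rho)/r_max
                          + w_sm  * 2ndSm
                          + w_cv  * CV(speed))

    All slope weights are non-negative, so DoS is monotone non-decreasing
    in each irregularity component.
    """

    w0: float = 0.21
    w_rms: float = 8.0
    w_sm: float = 0.9
    w_cv: float = 1.5


@dataclass(frozen=True)
class IndexConfig:
    """Parameters of the radius-angle transform and the six spiral indices."""

    center_k: int = 5              # samples averaged for the start-point center
    bins_per_rev: int = 360        # uniform angle grid resolution
    backtrack_tol: float = 0.05    # rad; larger backward angle steps are dropped
    tremor_cutoff_hz: float = 2.0  # low-pass cutoff before width computation
    zc_per_revolution: bool = True  # normalize zero-crossing count per turn
    zc_on_residual: bool = False    # count crossings of rho itself, not its diff
    dos_weights: DosWeights = field(default_factory=DosWeights)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = IndexConfig()

#: Seed recorded in config for fully default runs.
DEFAULT_SEED = 20161012
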