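import numpy as np
import pytest

import spiralkit as sk


@pytest.fixture(scope="session")
def ideal_trace() -> sk.SpiralTrace:
    """Noise-free Archimedean spiral: 5 turns, 0.9 cm spacing, 20 cm/s."""
    return sk.simulate_trace(sk.DrawingParams(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced case-control cohort (20 PD / 20 control, 3 trials/hand)."""
    metas, traces, truths = sk.generate_cohort(
        n_pd=20, n_control=20, n_early_pd=8, seed=11, trials_per_hand=3)
    return metas, traces, truths


@pytest.fixture(scope="session")
def small_records(small_cohort):
    metas, traces, _ = small_cohort
    table = sk.index_table(traces)
    return sk.subject_records(metas, table)


def make_trace(t, x, y, subject_id="t", hand="dominant", trial=1):
    return sk.SpiralTrace(subject_id, hand, trial,
                          np.asarray(t, float), np.asarray(x, float),
                          np.asarray(y, float))


@pytest.fixture
def archimedean_polar():
    """Exact polar trace r = 0.2*theta over 5 revolutions, on pen samples."""
    theta = np.linspace(0.0, 10 * np.pi, 1500)
    from spiralkit.polar import PolarTrace
    return PolarTrace(theta=theta, r=0.2 * theta, t=np.arange(1500) * 0.01,
                      center=(0.0, 0.0), direction="CCW")
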