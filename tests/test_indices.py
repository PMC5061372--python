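"""The six spiral indices: closed forms, oracles, scale laws, aggregation."""

import numpy as np
import pytest

import spiralkit as sk
from spiralkit.config import IndexConfig, DosWeights
from spiralkit.indices import (IndexComputationError, IndexSet,
                               aggregate_subject, degree_of_severity,
                               first_order_zero_crossings, mean_speed,
                               second_order_smoothness,
                               spiral_width_variability, tightness)
from spiralkit.io import SubjectMeta
from spiralkit.polar import PolarTrace, ResidualSeries, polar_pipeline

from conftest import make_trace

TWO_PI = 2 * np.pi


def residual_on_grid(rho, revolutions):
    n = rho.size
    grid = np.linspace(0.0, TWO_PI * revolutions, n)
    return ResidualSeries(theta_grid=grid, rho=rho, slope=0.14, intercept=0.0)


class TestMeanSpeed:
    def test_constant_speed_line(self):
        t = 0.001 * np.arange(5000)
        tr = make_trace(t, 20.0 * t, np.zeros_like(t))
        assert mean_speed(tr) == pytest.approx(20.0, abs=0.01)

    def test_time_dilation_halves_speed(self):
        t = 0.001 * np.arange(5000)
        tr = make_trace(2 * t, 20.0 * t, np.zeros_like(t))
        assert mean_speed(tr) == pytest.approx(10.0, abs=0.005)

    def test_unit_circle_in_two_pi_seconds(self):
        t = np.linspace(0, TWO_PI, 20000)
        tr = make_trace(t, np.cos(t), np.sin(t))
        assert mean_speed(tr) == pytest.approx(1.0, abs=0.001)

    def test_zero_elapsed_time_rejected(self):
        tr = make_trace([0.0, 0.0], [0, 1], [0, 0])
        with pytest.raises(IndexComputationError):
            mean_speed(tr)


class TestTightness:
    @staticmethod
    def polar(turns, r_max):
        th = np.linspace(0, TWO_PI * turns, 2000)
        return PolarTrace(theta=th, r=r_max * th / th[-1], t=th,
                          center=(0, 0), direction="CCW")

    def test_definition(self):
        assert tightness(self.polar(5, 5.0)) == pytest.approx(1.0, rel=1e-9)

    def test_micrographic_spiral(self):
        assert tightness(self.polar(6, 4.0)) == pytest.approx(1.5, rel=1e-9)

    def test_shrinking_doubles_tightness(self):
        tr = sk.simulate_trace(sk.DrawingParams(irregularity_sd=0.01), 5)
        x0, y0 = sk.estimate_center(tr)
        half = make_trace(tr.t, x0 + 0.5 * (tr.x - x0), y0 + 0.5 * (tr.y - y0))
        t1 = sk.compute_index_set(tr).T
        t2 = sk.compute_index_set(half).T
        assert t2 == pytest.approx(2 * t1, rel=1e-6)


class TestSecondOrderSmoothness:
    def test_sinusoid_closed_form(self):
        # rho = A sin(k theta): second derivative -A k^2 sin, mean square A^2 k^4 / 2
        grid_n = 4 * 360 + 1
        theta = np.linspace(0, 4 * TWO_PI, grid_n)
        res = residual_on_grid(0.1 * np.sin(5 * theta), 4)
        val = second_order_smoothness(res)
        assert val == pytest.approx(np.log(0.1 ** 2 * 5 ** 4 / 2), abs=0.02)

    def test_doubling_amplitude_adds_log_four(self):
        theta = np.linspace(0, 4 * TWO_PI, 1441)
        v1 = second_order_smoothness(residual_on_grid(0.1 * np.sin(5 * theta), 4))
        v2 = second_order_smoothness(residual_on_grid(0.2 * np.sin(5 * theta), 4))
        assert v2 - v1 == pytest.approx(np.log(4.0), abs=0.01)

    def test_ideal_spiral_hits_floor(self, ideal_trace):
        _, _, res = polar_pipeline(ideal_trace)
        assert second_order_smoothness(res) == pytest.approx(np.log(1e-12))


class TestFirstOrderZeroCrossings:
    def test_sinusoid_exact_count(self):
        theta = np.linspace(0, 2 * TWO_PI, 721)
        res = residual_on_grid(0.05 * np.sin(3 * theta), 2)
        assert first_order_zero_crossings(res) == pytest.approx(6.0)

    def test_constant_residual_has_no_crossings(self):
        res = residual_on_grid(np.zeros(1441), 4)
        assert first_order_zero_crossings(res) == 0.0

    def test_matches_brute_force_counting_oracle(self):
        rng = np.random.default_rng(7)
        rho = rng.normal(0, 0.05, 2 * 360 + 1)
        res = residual_on_grid(rho, 2)
        # independent oracle: walk the first differences, tracking last sign
        d = np.diff(rho)
        count, last = 0, 0
        for v in d:
            s = int(v > 0) - int(v < 0)
            if s == 0:
                continue
            if last != 0 and s != last:
                count += 1
            last = s
        assert first_order_zero_crossings(res) == pytest.approx(count / 2.0)

    def test_raw_count_and_residual_variant_flags(self):
        theta = np.linspace(0, 2 * TWO_PI, 721)
        rho = 0.05 * np.sin(3 * theta)
        res = residual_on_grid(rho, 2)
        raw = first_order_zero_crossings(
            res, IndexConfig(zc_per_revolution=False))
        assert raw == 12.0
        on_res = first_order_zero_crossings(
            res, IndexConfig(zc_on_residual=True))
        # sin(3 theta) over exactly 2 revolutions: 11 interior crossings
        # (the aligned endpoints are zeros, not transitions)
        assert on_res == pytest.approx(5.5)


def uniform_polar_from_r(r_of_theta, revolutions=5, bins=360, seconds=5.0):
    n = revolutions * bins + 1
    theta = np.linspace(0, TWO_PI * revolutions, n)
    r = r_of_theta(theta)
    t = np.linspace(0, seconds, n)
    return PolarTrace(theta=theta, r=r, t=t, center=(0, 0), direction="CCW",
                      uniform=True)


class TestSpiralWidthVariability:
    def test_ideal_spiral_zero_variability(self):
        polar = uniform_polar_from_r(lambda th: 0.15 * th)
        res = ResidualSeries(polar.theta, np.zeros_like(polar.theta), 0.15, 0.0)
        assert spiral_width_variability(res, polar) == pytest.approx(0.0, abs=1e-6)

    def test_half_plane_alternating_spacing(self):
        # loop spacing 0.8 cm for angles in [0, pi), 1.2 cm in [pi, 2 pi)
        def r_of(th):
            spacing = np.where(np.mod(th, TWO_PI) < np.pi, 0.8, 1.2)
            return spacing * th / TWO_PI
        polar = uniform_polar_from_r(r_of)
        res = ResidualSeries(polar.theta, np.zeros_like(polar.theta), 0.16, 0.0)
        # no tremor here: disable the low-pass so the half-plane step pattern
        # reaches the width computation unblurred
        cv = spiral_width_variability(res, polar,
                                      IndexConfig(tremor_cutoff_hz=0.0))
        # brute-force: medians are 0.8 on half the angles, 1.2 on the other
        medians = np.array([0.8] * 180 + [1.2] * 180)
        expect = medians.std() / medians.mean()
        assert cv == pytest.approx(expect, abs=0.01)

    def test_tremor_is_removed_by_filter(self):
        params = sk.DrawingParams(tremor_amp=0.1, tremor_freq=5.0)
        tr = sk.simulate_trace(params, 21)
        polar, uni, res = polar_pipeline(tr)
        filtered = spiral_width_variability(res, polar)
        unfiltered = spiral_width_variability(
            res, polar, IndexConfig(tremor_cutoff_hz=0.0))
        assert filtered < 0.02
        assert unfiltered > 2 * filtered

    def test_negative_mean_width_rejected(self):
        polar = uniform_polar_from_r(lambda th: 4.0 - 0.5 * th)
        res = ResidualSeries(polar.theta, np.zeros_like(polar.theta), -0.5, 4.0)
        with pytest.raises(IndexComputationError):
            spiral_width_variability(res, polar)


class TestDegreeOfSeverity:
    def test_ideal_spiral_is_normal(self, ideal_trace):
        assert sk.compute_index_set(ideal_trace).DoS < 1.0

    def test_maximal_degradation_is_severe(self):
        tr = sk.simulate_trace(sk.MAX_DEGRADATION, 13)
        assert sk.compute_index_set(tr).DoS > 3.0

    def test_monotone_in_radial_noise_amplitude(self):
        amps = [0.0, 0.05, 0.1, 0.25, 0.5]
        scores = []
        for a in amps:
            tr = sk.simulate_trace(sk.DrawingParams(irregularity_sd=a), 11)
            polar, uni, res = polar_pipeline(tr)
            scores.append(degree_of_severity(res, uni, tr))
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_missing_weights_is_config_error(self, ideal_trace):
        polar, uni, res = polar_pipeline(ideal_trace)
        cfg = IndexConfig(dos_weights=None)
        with pytest.raises(IndexComputationError, match="weights"):
            degree_of_severity(res, uni, ideal_trace, config=cfg)


class TestComputeIndexSet:
    def test_ideal_spiral_composition(self, ideal_trace):
        s = sk.compute_index_set(ideal_trace)
        assert s.T == pytest.approx(5.0 / 4.5, rel=0.01)
        assert s.mSp == pytest.approx(20.0, rel=0.01)
        assert s.SWVI < 1e-3
        assert s.FirstZC == 0.0
        assert s.SecondSm == pytest.approx(np.log(1e-12))
        assert s.DoS < 1.0

    def test_deterministic(self, ideal_trace):
        assert sk.compute_index_set(ideal_trace) == sk.compute_index_set(ideal_trace)

    def test_group_presets_shift_indices_in_expected_directions(self):
        rng = np.random.default_rng(3)
        pd_sets, ct_sets = [], []
        for _ in range(25):
            ct_sets.append(sk.compute_index_set(
                sk.simulate_trace(sk.CONTROL_PRESET.draw_params(rng), rng)))
            pd_sets.append(sk.compute_index_set(
                sk.simulate_trace(sk.PD_PRESET.draw_params(rng), rng)))
        mean = lambda sets, nm: np.mean([getattr(s, nm) for s in sets])
        assert mean(pd_sets, "T") > mean(ct_sets, "T")
        assert mean(pd_sets, "mSp") < mean(ct_sets, "mSp")
        assert mean(pd_sets, "SWVI") > mean(ct_sets, "SWVI")

    def test_straight_line_reimplementation_oracle(self):
        """Each index recomputed with plain loops from the shared transform."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            params = sk.DrawingParams(
                loop_spacing=rng.uniform(0.6, 0.95),
                base_speed=rng.uniform(10, 30),
                irregularity_sd=rng.uniform(0.005, 0.03),
                tremor_amp=rng.uniform(0, 0.01),
                width_drift_amp=rng.uniform(0.05, 0.3))
            tr = sk.simulate_trace(params, rng)
            got = sk.compute_index_set(tr)
            polar, uni, res = polar_pipeline(tr)
            # mean speed
            path = sum(float(np.hypot(tr.x[i + 1] - tr.x[i], tr.y[i + 1] - tr.y[i]))
                       for i in range(len(tr) - 1))
            assert got.mSp == pytest.approx(path / (tr.t[-1] - tr.t[0]), abs=1e-9)
            # tightness: angular span extended to the r = 0 intercept of the
            # radius line (the trimmed center sliver), capped at half a turn
            th, rr = uni.theta, uni.r
            sxx = np.sum((th - th.mean()) ** 2)
            b_hat = np.sum((th - th.mean()) * (rr - rr.mean())) / sxx
            a_hat = rr.mean() - b_hat * th.mean()
            span = th[-1] - th[0]
            if b_hat > 1e-6 and a_hat > 0:
                span += min(a_hat / b_hat, np.pi)
            assert got.T == pytest.approx(span / TWO_PI / max(rr), abs=1e-9)
            # smoothness
            h = res.theta_grid[1] - res.theta_grid[0]
            d2 = [(res.rho[i + 1] - 2 * res.rho[i] + res.rho[i - 1]) / h ** 2
                  for i in range(1, res.rho.size - 1)]
            assert got.SecondSm == pytest.approx(
                np.log(max(np.mean(np.square(d2)), 1e-12)), abs=1e-9)


class TestScaleLaws:
    def test_spatial_shrink(self, noisy_scaled_trace=None):
        tr = sk.simulate_trace(sk.DrawingParams(
            irregularity_sd=0.01, width_drift_amp=0.15), 9)
        s = 0.5
        x0, y0 = sk.estimate_center(tr)
        small = make_trace(tr.t, x0 + s * (tr.x - x0), y0 + s * (tr.y - y0))
        a, b = sk.compute_index_set(tr), sk.compute_index_set(small)
        assert b.T == pytest.approx(a.T / s, rel=1e-6)
        assert b.mSp == pytest.approx(a.mSp * s, rel=1e-6)
        assert b.SWVI == pytest.approx(a.SWVI, rel=1e-6)
        assert b.FirstZC == pytest.approx(a.FirstZC, abs=1e-9)

    def test_time_rescale(self):
        tr = sk.simulate_trace(sk.DrawingParams(
            irregularity_sd=0.01, width_drift_amp=0.15), 9)
        c = 2.0
        slow = make_trace(c * tr.t, tr.x, tr.y)
        a, b = sk.compute_index_set(tr), sk.compute_index_set(slow)
        assert b.mSp == pytest.approx(a.mSp / c, rel=1e-9)
        assert b.T == pytest.approx(a.T, rel=1e-9)
        assert b.FirstZC == pytest.approx(a.FirstZC, abs=1e-9)

    def test_irregularity_monotonicity_of_smoothness_and_swvi(self):
        """2ndSm is non-decreasing in the irregularity amplitude; SWVI in the
        width-drift amplitude (5-point sweeps, fixed seed)."""
        sm = []
        for a in (0.0, 0.01, 0.03, 0.08, 0.2):
            tr = sk.simulate_trace(sk.DrawingParams(irregularity_sd=a), 31)
            sm.append(sk.compute_index_set(tr).SecondSm)
        assert all(y >= x for x, y in zip(sm, sm[1:]))
        sw = []
        for a in (0.0, 0.1, 0.2, 0.3, 0.4):
            tr = sk.simulate_trace(sk.DrawingParams(width_drift_amp=a), 31)
            sw.append(sk.compute_index_set(tr).SWVI)
        assert all(y >= x for x, y in zip(sw, sw[1:]))


class TestAggregation:
    @staticmethod
    def iset(**kw):
        base = dict(DoS=1.0, SecondSm=-3.0, FirstZC=3.0, T=1.2, mSp=20.0,
                    SWVI=0.2)
        base.update(kw)
        return IndexSet(**base)

    def test_identical_trials_give_zero_differences(self):
        meta = SubjectMeta("s1", "control", 60, "F", "right")
        sets = {(h, k): self.iset() for h in ("dominant", "nondominant")
                for k in (1, 2)}
        rec = aggregate_subject(meta, sets)
        assert all(v == 0 for v in rec.diff.as_dict().values())

    def test_mean_aggregation_arithmetic(self):
        meta = SubjectMeta("s1", "control", 60, "F", "right")
        sets = {("dominant", 1): self.iset(DoS=1.0),
                ("dominant", 2): self.iset(DoS=2.0),
                ("nondominant", 1): self.iset(DoS=1.2),
                ("nondominant", 2): self.iset(DoS=1.4)}
        rec = aggregate_subject(meta, sets)
        assert rec.dom.DoS == pytest.approx(1.5)
        assert rec.nondom.DoS == pytest.approx(1.3)
        assert rec.diff.DoS == pytest.approx(0.2)

    def test_swvi_uses_median_not_mean(self):
        meta = SubjectMeta("s1", "control", 60, "F", "right")
        sets = {("dominant", k): self.iset(SWVI=v)
                for k, v in enumerate([0.1, 0.2, 0.9], start=1)}
        sets[("nondominant", 1)] = self.iset(SWVI=0.2)
        rec = aggregate_subject(meta, sets)
        assert rec.dom.SWVI == pytest.approx(0.2)

    def test_missing_hand_rejected(self):
        meta = SubjectMeta("s1", "control", 60, "F", "right")
        with pytest.raises(IndexComputationError, match="nondominant"):
            aggregate_subject(meta, {("dominant", 1): self.iset()})
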