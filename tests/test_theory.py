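"""Unit tests for the closed-form SNR theory and its optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import lfilter

from spikesnr.theory import (
    DegenerateGeometryError,
    DetectorGeometry,
    InfeasibleConstraintError,
    TheoryParams,
    expected_M,
    expected_r,
    expected_snr,
    noise_stats,
    optimize_snr,
    reduced_snr_sample,
    v_max,
)


class TestTheoryParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=0, f=1.0, T=0.0, P=1, L=10.0),
            dict(N=10, f=0.0, T=0.0, P=1, L=10.0),
            dict(N=10, f=1.0, T=-1.0, P=1, L=10.0),
            dict(N=10, f=1.0, T=0.0, P=0, L=10.0),
            dict(N=10, f=1.0, T=0.0, P=1, L=0.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TheoryParams(**kwargs)


class TestVmax:
    def test_zero_jitter_limit_is_charging_curve(self):
        # T -> 0 reduces to 1 - exp(-dt/tau); the small-T branch must agree
        # with the general formula evaluated just above the threshold.
        for dt_w, tau in [(5.0, 5.0), (11.0, 8.9), (1.0, 20.0)]:
            assert v_max(dt_w, 0.0, tau) == pytest.approx(1.0 - np.exp(-dt_w / tau), abs=1e-9)
            assert v_max(dt_w, 1e-5, tau) == pytest.approx(v_max(dt_w, 0.0, tau), abs=1e-4)

    def test_charging_curve_at_dt_equal_tau(self):
        assert v_max(8.9, 0.0, 8.9) == pytest.approx(1.0 - np.exp(-1.0), abs=1e-12)

    def test_long_window_saturates_at_one(self):
        assert v_max(1e6, 3.2, 8.9) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_packet_oracle(self):
        # Oracle: threshold-free LIF driven by a dense spike packet of
        # duration dt with per-spike uniform jitter in [-T, T]; the peak,
        # normalized by the steady state tau*rate, realizes the reduced peak.
        rng = np.random.default_rng(42)
        dt_w, T, tau = 11.0, 3.2, 8.9
        n_spikes = 400_000
        arrivals = rng.uniform(0, dt_w, n_spikes) + rng.uniform(-T, T, n_spikes)
        h = 0.005
        counts = np.bincount(np.floor((arrivals - arrivals.min()) / h).astype(int)).astype(float)
        V = lfilter([1.0], [1.0, -(1 - h / tau)], counts)
        vmax_mc = V.max() / (tau * n_spikes / dt_w)
        assert vmax_mc == pytest.approx(v_max(dt_w, T, tau), rel=0.01)
        assert v_max(dt_w, T, tau) == pytest.approx(0.63, abs=0.01)

    @given(
        dt_w=st.floats(0.1, 100.0),
        T=st.floats(0.0, 20.0),
        tau=st.floats(0.5, 100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, dt_w, T, tau):
        v = v_max(dt_w, T, tau)
        assert 0.0 <= v <= 1.0
        assert v_max(dt_w * 1.5, T, tau) >= v - 1e-12  # non-decreasing in dt
        assert v_max(dt_w, T + 1.0, tau) <= v + 1e-12  # non-increasing in T

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            v_max(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            v_max(1.0, 1.0, -1.0)


class TestExpectedM:
    def test_reference_point(self, reference_params):
        # N=1e4, f=3.2 Hz, P=5, dt=11 ms -> ~1614 connected afferents
        assert expected_M(reference_params, 11.0) == pytest.approx(1614, abs=2)

    def test_zero_window(self, reference_params):
        assert expected_M(reference_params, 0.0) == 0.0

    def test_monte_carlo_oracle(self):
        # count afferents with >= 1 spike in a 2 ms window at 1 Hz
        params = TheoryParams(N=10_000, f=1.0, T=0.0, P=1, L=100.0)
        rng = np.random.default_rng(7)
        lam = params.f / 1000.0 * 2.0
        n_rep = 2000
        counts = rng.poisson(lam, size=(n_rep, params.N))
        m_emp = (counts > 0).sum(axis=1).mean()
        m_th = expected_M(params, 2.0)
        assert m_th == pytest.approx(19.98, abs=0.01)
        sd = np.sqrt(params.N * lam * (1 - lam)) / np.sqrt(n_rep)
        assert abs(m_emp - m_th) < 3 * sd + 0.3

    def test_monotone_and_bounded(self):
        base = TheoryParams(N=1000, f=2.0, T=0.0, P=3, L=50.0)
        grid = np.linspace(0.5, 50.0, 30)
        vals = expected_M(base, grid)
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals <= base.N)
        more_p = TheoryParams(N=1000, f=2.0, T=0.0, P=6, L=50.0)
        assert expected_M(more_p, 10.0) > expected_M(base, 10.0)

    def test_window_beyond_pattern_rejected(self, reference_params):
        with pytest.raises(ValueError):
            expected_M(reference_params, reference_params.L + 1.0)


class TestExpectedR:
    def test_product(self, reference_params):
        assert expected_r(reference_params) == pytest.approx(32_000.0)


class TestNoiseStats:
    def test_no_inputs(self):
        assert noise_stats(8.9, 3.2, 0) == (0.0, 0.0)

    def test_moment_scaling(self):
        m1, s1 = noise_stats(8.9, 3.2, 800)
        m2, s2 = noise_stats(8.9, 3.2, 1600)
        assert m2 == pytest.approx(2 * m1)
        assert s2 == pytest.approx(np.sqrt(2) * s1)

    def test_euler_simulation_oracle(self):
        # long threshold-free run under Poisson drive reproduces the
        # shot-noise moments mean = tau f M, sd = sqrt(tau f M / 2)
        tau, f, M = 8.9, 3.2, 1614
        mean_th, sd_th = noise_stats(tau, f, M)
        assert mean_th == pytest.approx(45.97, abs=0.01)
        assert sd_th == pytest.approx(4.79, abs=0.01)
        rng = np.random.default_rng(11)
        h = 0.1
        n = int(200_000.0 / h)
        drive = rng.poisson(M * f / 1000.0 * h, n).astype(float)
        V = lfilter([1.0], [1.0, -(1 - h / tau)], drive)[int(50 * tau / h) :]
        assert V.mean() == pytest.approx(mean_th, rel=0.02)
        assert V.std() == pytest.approx(sd_th, rel=0.03)


class TestExpectedSnr:
    def test_reference_optimum(self, reference_params):
        geom = DetectorGeometry.from_params(reference_params, tau=8.9, dt_window=11.0)
        comps = expected_snr(reference_params, geom)
        assert comps.snr == pytest.approx(31.0, abs=0.5)
        assert 0.0 <= comps.v_max <= 1.0
        assert comps.V_noise_sd > 0

    def test_many_patterns_geometry(self):
        params = TheoryParams(N=10_000, f=3.2, T=3.2, P=40, L=100.0)
        geom = DetectorGeometry.from_params(params, tau=5.1, dt_window=3.7)
        assert expected_snr(params, geom).snr == pytest.approx(6.7, abs=0.1)

    def test_tiny_window_kills_snr(self, reference_params):
        geom = DetectorGeometry.from_params(reference_params, tau=8.9, dt_window=1e-4)
        assert expected_snr(reference_params, geom).snr < 0.2

    def test_scales_with_n(self):
        a = TheoryParams(N=5_000, f=3.2, T=3.2, P=5, L=100.0)
        b = TheoryParams(N=10_000, f=3.2, T=3.2, P=5, L=100.0)
        ga = DetectorGeometry.from_params(a, 8.9, 11.0)
        gb = DetectorGeometry.from_params(b, 8.9, 11.0)
        assert expected_snr(b, gb).snr > expected_snr(a, ga).snr

    def test_degenerate_geometry_raises(self, reference_params):
        geom = DetectorGeometry(tau=8.9, dt_window=0.0, M_expected=0.0, r_expected=32_000.0)
        with pytest.raises(DegenerateGeometryError):
            expected_snr(reference_params, geom)


class TestOptimizeSnr:
    def test_matches_dense_grid_oracle(self, reference_params):
        res = optimize_snr(reference_params)
        taus = np.geomspace(0.5, 100.0, 500)
        dts = np.geomspace(0.1, 100.0, 500)
        tt, dd = np.meshgrid(taus, dts, indexing="ij")
        p = reference_params
        M = p.N * -np.expm1(-p.P * p.f / 1000.0 * dd)
        grid = (
            v_max(dd, p.T, tt)
            * np.sqrt(2 * tt / 1000.0 / p.f)
            * (p.f * p.N - p.f * M)
            / np.sqrt(M)
        )
        i = np.unravel_index(np.argmax(grid), grid.shape)
        assert res.components.snr >= grid[i] - 1e-6
        assert res.geometry.tau == pytest.approx(tt[i], rel=0.05)
        assert res.geometry.dt_window == pytest.approx(dd[i], rel=0.05)

    def test_snr_decreases_with_p_and_t(self):
        snrs = [
            optimize_snr(TheoryParams(N=10_000, f=3.2, T=3.2, P=P, L=100.0)).components.snr
            for P in (5, 10, 20, 40)
        ]
        assert np.all(np.diff(snrs) < 0)
        snr_t = [
            optimize_snr(TheoryParams(N=10_000, f=3.2, T=T, P=5, L=100.0)).components.snr
            for T in (1.0, 3.2, 10.0)
        ]
        assert np.all(np.diff(snr_t) < 0)

    def test_active_constraint_reported(self):
        # sparse, small problems push tau up until tau*f*<M> pins at the bound
        res = optimize_snr(TheoryParams(N=1000, f=1.0, T=1.0, P=1, L=50.0))
        tfm = res.geometry.tau / 1000.0 * 1.0 * res.geometry.M_expected
        assert res.constraint_active
        assert tfm == pytest.approx(10.0, rel=1e-3)

    def test_infeasible_constraint_raises(self):
        with pytest.raises(InfeasibleConstraintError):
            optimize_snr(TheoryParams(N=5, f=1.0, T=1.0, P=1, L=50.0))

    def test_dt_bound_enforced(self):
        params = TheoryParams(N=10_000, f=3.2, T=3.2, P=5, L=5.0)
        res = optimize_snr(params)
        assert res.geometry.dt_window <= params.L + 1e-9


class TestReducedSnrSample:
    def test_deterministic_under_seed(self):
        params = TheoryParams(N=1000, f=1.0, T=0.0, P=1, L=100.0)
        a = reduced_snr_sample(params, 2.0, 50, seed=3)
        b = reduced_snr_sample(params, 2.0, 50, seed=3)
        assert np.array_equal(a.samples, b.samples)
        assert a.n_excluded == b.n_excluded

    def test_mean_near_plug_in(self):
        params = TheoryParams(N=10_000, f=1.0, T=0.0, P=1, L=100.0)
        s = reduced_snr_sample(params, 2.0, 20_000, seed=4)
        assert s.samples.mean() == pytest.approx(s.plug_in, rel=0.02)
        # realization-to-realization variability is small
        assert s.samples.std() / s.samples.mean() < 0.2

    def test_empty_draws_excluded_and_counted(self):
        params = TheoryParams(N=2, f=0.5, T=0.0, P=1, L=100.0)
        s = reduced_snr_sample(params, 1.0, 500, seed=5)
        assert s.n_excluded > 0
        assert s.samples.size + s.n_excluded == 500
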