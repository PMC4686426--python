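"""Closed-form diffusion theory against independent numeric oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize

from paracrine.theory import (
    TheoryParams,
    advection_distance,
    advection_error,
    compare_decoding_weights,
    concentration,
    detection_radius,
    detection_threshold,
    diffusion_time,
    integration_time,
    pcd_closed_form,
    peclet,
    peclet_from_signal,
    signal_strength_for_pcd,
    time_averaged_concentration,
)

P0 = TheoryParams()  # rho=10, h_c=15, h_f=60, N_r=1e5, N_d=100, D=50, v=0.3


def numeric_max_detection_radius(p):
    """Independent oracle: maximize the detectable radius over a log-time grid
    followed by bounded scalar refinement."""
    ts = np.logspace(-3, 9, 600)
    rs, _ = detection_radius(ts, p)
    i = int(np.argmax(rs))
    res = optimize.minimize_scalar(
        lambda t: -detection_radius(t, p)[0][()],
        bounds=(ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return -res.fun, float(res.x)


class TestConcentration:
    def test_peak_value(self):
        c = concentration(0.0, 100.0, P0)
        assert c == pytest.approx(P0.N_r / (P0.h_f * 4 * math.pi * P0.D * 100.0))

    def test_mass_conservation(self):
        t = 50.0
        total, _ = integrate.quad(
            lambda r: concentration(r, t, P0) * P0.h_f * 2 * math.pi * r, 0, np.inf
        )
        assert total == pytest.approx(P0.N_r, rel=1e-6)

    def test_efold_radius(self):
        t = 30.0
        r = math.sqrt(4 * P0.D * t)
        assert concentration(r, t, P0) == pytest.approx(concentration(0.0, t, P0) / math.e)

    def test_requires_positive_time(self):
        with pytest.raises(ValueError):
            concentration(10.0, 0.0, P0)


class TestDetection:
    def test_threshold_arithmetic(self):
        assert detection_threshold(P0) == pytest.approx(100 / (15 * math.pi * 100))

    def test_threshold_linear_in_nd(self):
        p2 = TheoryParams(N_d=200.0)
        assert detection_threshold(p2) == pytest.approx(2 * detection_threshold(P0))

    def test_radius_at_log_argument_e(self):
        # arg = e  =>  r = 2 sqrt(D t)
        t = P0.rho**2 * P0.h_c * P0.N_r / (4 * P0.D * P0.N_d * P0.h_f) / math.e
        r, ok = detection_radius(t, P0)
        assert ok and r == pytest.approx(2 * math.sqrt(P0.D * t))

    def test_radius_matches_root_finding_oracle(self):
        c_det = detection_threshold(P0)
        for t in np.logspace(0, 3, 12):
            r, ok = detection_radius(float(t), P0)
            if not ok:
                continue
            root = optimize.brentq(
                lambda rr: concentration(rr, t, P0) - c_det, 1e-9, 1e5
            )
            assert r == pytest.approx(root, abs=1e-6)

    def test_dilute_limit_flagged_zero(self):
        r, ok = detection_radius(1e12, P0)
        assert r == 0.0 and not ok


class TestClosedForms:
    def test_pcd_value(self):
        p = TheoryParams(N_r=1e5, N_d=100.0)  # eta 0.25, S 1000
        assert pcd_closed_form(p) == pytest.approx(math.exp(-0.5) * 10 * math.sqrt(250))

    def test_pcd_matches_numeric_maximization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = TheoryParams(
                rho=rng.uniform(5, 20),
                h_c=rng.uniform(5, 30),
                h_f=rng.uniform(30, 120),
                N_r=rng.uniform(1e4, 1e6),
                N_d=rng.uniform(10, 1000),
                D=rng.uniform(1, 2000),
            )
            r_num, t_num = numeric_max_detection_radius(p)
            assert r_num == pytest.approx(pcd_closed_form(p), rel=1e-6)
            assert t_num == pytest.approx(integration_time(p), rel=1e-4)

    def test_pcd_independent_of_diffusion_coefficient(self):
        vals = []
        for D in (1.0, 10.0, 100.0, 2000.0):
            p = TheoryParams(D=D)
            r_num, _ = numeric_max_detection_radius(p)
            vals.append(r_num)
        assert np.ptp(vals) / np.mean(vals) < 1e-6

    def test_pcd_sqrt_scaling_in_signal(self):
        p4 = TheoryParams(N_r=4e5)
        assert pcd_closed_form(p4) == pytest.approx(2 * pcd_closed_form(P0))

    def test_integration_time_halves_with_double_d(self):
        assert integration_time(TheoryParams(D=100.0)) == pytest.approx(
            integration_time(P0) / 2
        )

    def test_signal_strength_inversion(self):
        s = signal_strength_for_pcd(100.0, 10.0, 0.25)
        p = TheoryParams(N_r=s * 100.0, N_d=100.0)
        assert pcd_closed_form(p) == pytest.approx(100.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(0.5, 3.0))
    def test_dimensional_rescaling(self, c):
        # lengths x c, times x c^2, D invariant: PCD scales by c, T_int by c^2
        p = TheoryParams()
        ps = TheoryParams(rho=p.rho * c, h_c=p.h_c * c, h_f=p.h_f * c)
        assert pcd_closed_form(ps) == pytest.approx(c * pcd_closed_form(p), rel=1e-12)
        assert integration_time(ps) == pytest.approx(
            c**2 * integration_time(p), rel=1e-12
        )


class TestFlowAndDecoding:
    def test_diffusion_time_values(self):
        assert diffusion_time(50.0, 50.0) == pytest.approx(12.5)
        assert diffusion_time(0.0, 50.0) == 0.0
        assert diffusion_time(100.0, 50.0) == pytest.approx(50.0)

    def test_peclet_arithmetic(self):
        assert peclet(0.3, 100.0, 60.0) == pytest.approx(0.5)
        assert peclet(0.0, 100.0, 60.0) == 0.0

    def test_peclet_signal_form_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = TheoryParams(
                rho=rng.uniform(5, 20),
                N_r=rng.uniform(1e4, 1e6),
                N_d=rng.uniform(10, 1000),
                D=rng.uniform(5, 500),
                v=rng.uniform(0.05, 1.0),
            )
            assert peclet_from_signal(p) == pytest.approx(
                peclet(p.v, pcd_closed_form(p), p.D), rel=1e-12
            )

    def test_advection_error_fraction(self):
        assert advection_error(50.0, 500.0) == pytest.approx(0.10)
        assert advection_error(0.0, 500.0) == 0.0
        assert advection_distance(0.5, 100.0) == pytest.approx(50.0)

    def test_time_average_matches_quadrature(self):
        for r in (10.0, 50.0, 200.0, 500.0):
            for t0 in (10.0, 300.0, 1000.0):
                val = time_averaged_concentration(r, t0, P0)
                num, _ = integrate.quad(
                    lambda t: concentration(r, t, P0) / t0, 0, t0,
                    epsabs=0, epsrel=1e-12, limit=200,
                )
                assert val == pytest.approx(num, rel=1e-8)

    def test_time_average_monotone_decreasing_and_linear_in_nr(self):
        r = np.linspace(20, 500, 50)
        c = time_averaged_concentration(r, 300.0, P0)
        assert np.all(np.diff(c) < 0)
        c2 = time_averaged_concentration(r, 300.0, TheoryParams(N_r=2e5))
        assert np.allclose(c2, 2 * c)

    def test_time_average_rejects_source_point(self):
        with pytest.raises(ValueError):
            time_averaged_concentration(0.0, 300.0, P0)

    def test_decoding_weight_profiles_similar_beyond_50um(self):
        table, disc, t0 = compare_decoding_weights(100.0, P0)
        assert disc < 0.15
        assert t0 > 0
        # both profiles decrease with distance
        assert np.all(np.diff(table["gaussian"]) < 0)
        assert np.all(np.diff(table["temporal"]) < 0)
        # discrepancy is largest below 50 um (instantaneous-release artifact)
        below = table[table["r"] < 50.0]
        gap_below = np.abs(below["gaussian"] - below["temporal"]).max()
        assert gap_below > disc
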