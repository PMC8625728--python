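"""Hitting fraction of the n-receptor sphere and the pulsed arrival model."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import receptorq as rq

# direct-arithmetic reference values for the Table-1 geometry
PLATEAU = 0.07885623676048051          # (Rr/d) * n*rs/(n*rs + pi*Rr)
STEADY_Q50 = 394.28118380240255        # 5000/s * PLATEAU


class TestStokesEinstein:
    def test_physiological_value(self):
        # 310 K, blood-plasma-like viscosity, 1.75 nm molecule radius
        D = rq.stokes_einstein_D(310.0, 1.1e-3, 1.75e-9)
        assert D == pytest.approx(1.18e-10, rel=0.03)

    def test_inverse_proportional_to_radius(self):
        D1 = rq.stokes_einstein_D(310.0, 1.1e-3, 1.75e-9)
        D2 = rq.stokes_einstein_D(310.0, 1.1e-3, 3.5e-9)
        assert D2 == pytest.approx(D1 / 2.0, rel=1e-14)

    @pytest.mark.parametrize("T,eta,rm", [(0, 1e-3, 1e-9), (300, -1e-3, 1e-9),
                                          (300, 1e-3, 0)])
    def test_nonpositive_input_rejected(self, T, eta, rm):
        with pytest.raises(ValueError):
            rq.stokes_einstein_D(T, eta, rm)


class TestFhitCumulative:
    def test_zero_at_time_zero(self, table1):
        assert rq.fhit_cumulative(0.0, table1.geometry, table1.medium.D) == 0.0

    def test_negative_time_rejected(self, table1):
        with pytest.raises(ValueError):
            rq.fhit_cumulative(-1.0, table1.geometry, table1.medium.D)

    def test_long_time_plateau(self, table1):
        # analytic t->inf limit: the bracket converges to 1
        geom = table1.geometry
        assert rq.fhit_infinity(geom) == pytest.approx(PLATEAU, rel=1e-12)
        assert rq.fhit_cumulative(1e9, geom, table1.medium.D) == pytest.approx(
            PLATEAU, rel=1e-3)

    def test_absorbing_sphere_limit_at_high_receptor_density(self, table1):
        # n -> inf collapses onto the classic first-passage CDF
        g = table1.geometry
        with pytest.warns(UserWarning):  # receptor area exceeds the surface
            dense = rq.GeometryParams(Rr=g.Rr, rs=g.rs, n=10**9, d=g.d)
        got = rq.fhit_cumulative(1.0, dense, table1.medium.D)
        ref = rq.absorbing_sphere_cdf(1.0, g.Rr, g.d, table1.medium.D)
        assert got == pytest.approx(ref, rel=1e-4)

    def test_nondecreasing_and_bounded_on_log_grid(self, table1):
        t = np.logspace(-3, 3, 200)
        f = rq.fhit_cumulative(t, table1.geometry, table1.medium.D)
        assert np.all(np.diff(f) >= -1e-15)
        assert np.all(f < rq.fhit_infinity(table1.geometry) * (1 + 1e-12))
        assert np.all(f >= 0)

    def test_increases_with_receptor_count(self, table1):
        g = table1.geometry
        vals = [float(rq.fhit_cumulative(
            1.0, rq.GeometryParams(Rr=g.Rr, rs=g.rs, n=n, d=g.d), table1.medium.D))
            for n in (50, 100, 1000, 5000, 10000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_numerically_stable_at_extreme_times(self, table1):
        # the naive exp(A)*erfc(B) form overflows here; the erfcx rewrite must not
        t = np.array([1e-6, 1e-2, 1.0, 1e4, 1e8, 1e12])
        f = rq.fhit_cumulative(t, table1.geometry, table1.medium.D)
        assert np.all(np.isfinite(f)) and np.all((f >= 0) & (f < 1))


class TestFhitWindow:
    def test_empty_window_is_zero(self, table1):
        assert rq.fhit_window(2.0, 2.0, table1.geometry, table1.medium.D) == 0.0

    def test_window_from_origin_equals_cumulative(self, table1):
        got = rq.fhit_window(0.0, 3.0, table1.geometry, table1.medium.D)
        assert got == pytest.approx(
            float(rq.fhit_cumulative(3.0, table1.geometry, table1.medium.D)), abs=1e-15)

    def test_reversed_window_rejected(self, table1):
        with pytest.raises(ValueError):
            rq.fhit_window(2.0, 1.0, table1.geometry, table1.medium.D)

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8))
    def test_partition_telescopes(self, cuts):
        cfg = rq.load_fixture("table1_q50_mu4")
        edges = np.concatenate([[0.0], np.sort(cuts)])
        total = sum(rq.fhit_window(a, b, cfg.geometry, cfg.medium.D)
                    for a, b in zip(edges, edges[1:]))
        assert total == pytest.approx(
            float(rq.fhit_cumulative(edges[-1], cfg.geometry, cfg.medium.D)), abs=1e-12)


class TestAbsorptionRate:
    def test_zero_at_time_zero(self, table1):
        assert rq.rabsorb_rate(0.0, table1.geometry, table1.medium.D,
                               table1.emission) == 0.0

    def test_steady_state_value(self, table1):
        got = rq.rabsorb_steady(table1.geometry, table1.medium.D, table1.emission)
        assert got == pytest.approx(STEADY_Q50, rel=1e-12)

    def test_steady_equals_emission_rate_times_plateau_limit(self, table1):
        # Fhit has converged to within 0.1% of its plateau only at very long
        # times (the approach is ~ 1 - 2*(d-Rr)/sqrt(4*pi*D*t))
        rate_limit = table1.emission.rate * rq.fhit_cumulative(
            1e7, table1.geometry, table1.medium.D)
        assert rate_limit == pytest.approx(STEADY_Q50, rel=1e-3)

    def test_matches_continuous_emission_form(self, table1):
        # on the pulse-aligned grid the pulse sum telescopes to (Q/dt)*Fhit(t)
        # (within the emission horizon; pulses stop at t_end)
        for t in (1.0, 5.0, 10.0):
            got = rq.rabsorb_rate(t, table1.geometry, table1.medium.D, table1.emission)
            ref = table1.emission.rate * rq.fhit_cumulative(
                t, table1.geometry, table1.medium.D)
            assert got == pytest.approx(ref, rel=0.005)

    def test_linear_in_pulse_size(self, table1):
        e = table1.emission
        e2 = rq.EmissionSchedule(Q=2 * e.Q, delta_t=e.delta_t, t_end=e.t_end)
        r1 = rq.rabsorb_rate(4.0, table1.geometry, table1.medium.D, e)
        r2 = rq.rabsorb_rate(4.0, table1.geometry, table1.medium.D, e2)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_stable_under_grid_refinement(self, table1):
        coarse = rq.rabsorb_rate(5.0, table1.geometry, table1.medium.D,
                                 table1.emission, grid_dt=0.01)
        fine = rq.rabsorb_rate(5.0, table1.geometry, table1.medium.D,
                               table1.emission, grid_dt=0.005)
        assert fine == pytest.approx(coarse, rel=0.005)

    def test_per_receptor_rate_scales_by_n(self, table1):
        g = table1.geometry
        r = rq.rabsorb_rate(3.0, g, table1.medium.D, table1.emission)
        assert rq.lambda_o(3.0, g, table1.medium.D, table1.emission) == pytest.approx(
            r / g.n, rel=1e-14)
        single = rq.GeometryParams(Rr=g.Rr, rs=g.rs, n=1, d=g.d)
        assert rq.lambda_o(3.0, single, table1.medium.D, table1.emission) == \
            pytest.approx(rq.rabsorb_rate(3.0, single, table1.medium.D,
                                          table1.emission), rel=1e-14)

    def test_steady_receptor_factor_vanishes_for_dense_coverage(self, table1):
        g = table1.geometry
        with pytest.warns(UserWarning):
            dense = rq.GeometryParams(Rr=g.Rr, rs=g.rs, n=10**9, d=g.d)
        got = rq.rabsorb_steady(dense, table1.medium.D, table1.emission)
        assert got == pytest.approx(table1.emission.rate * g.Rr / g.d, rel=1e-4)
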