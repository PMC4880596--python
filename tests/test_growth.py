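"""Growth curves, element discretization, pruning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroplast.calcium import CalciumParams
from neuroplast.growth import (
    ElementArray,
    ElementPool,
    GrowthCurveSpec,
    growth_rate,
    integrate_elements,
    prune_vacant,
)

CAL = CalciumParams(tau=10000.0, beta=0.001)
LIN = GrowthCurveSpec("linear", nu=1e-4, eps=0.05)
GAU = GrowthCurveSpec("gaussian", nu=1e-4, eps=0.05, eta=0.0)


class TestGrowthRate:
    def test_linear_at_zero_and_setpoint(self):
        assert growth_rate(LIN, 0.0) == pytest.approx(LIN.nu)
        assert growth_rate(LIN, LIN.eps) == pytest.approx(0.0, abs=1e-18)

    def test_gaussian_peak_at_xi(self):
        assert growth_rate(GAU, GAU.xi) == pytest.approx(GAU.nu)

    def test_gaussian_zero_crossings_at_eta_and_eps(self):
        # ((eps - xi)/zeta)^2 = ln 2  =>  2 e^{-ln 2} - 1 = 0, same at eta
        g = GrowthCurveSpec("gaussian", nu=2e-4, eps=0.3, eta=0.1)
        assert growth_rate(g, g.eps) == pytest.approx(0.0, abs=1e-18)
        assert growth_rate(g, g.eta) == pytest.approx(0.0, abs=1e-18)

    def test_gaussian_saturates_at_minus_nu(self):
        assert growth_rate(GAU, 100 * GAU.eps) == pytest.approx(-GAU.nu)

    def test_derived_xi_zeta(self):
        g = GrowthCurveSpec("gaussian", nu=1.0, eps=0.3, eta=0.1)
        assert g.xi == pytest.approx(0.2)
        assert g.zeta == pytest.approx(0.2 / (2 * math.sqrt(math.log(2))))

    @given(st.floats(0.0, 1.0), st.floats(1e-6, 0.5))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_gaussian_sign_pattern_and_symmetry(self, ca, eta_frac):
        eps = 0.4
        eta = eta_frac * eps * 0.9
        g = GrowthCurveSpec("gaussian", nu=1e-3, eps=eps, eta=eta)
        rate = growth_rate(g, ca)
        if eta < ca < eps:
            assert rate > 0
        elif ca < eta or ca > eps:
            assert rate < 0
        mirrored = growth_rate(g, 2 * g.xi - ca)
        if 2 * g.xi - ca >= 0:
            assert rate == pytest.approx(mirrored, rel=1e-9, abs=1e-15)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_linear_strictly_decreasing(self, a, b):
        lo, hi = min(a, b), max(a, b)
        if hi - lo < 1e-9:  # below float resolution of the rate difference
            return
        assert growth_rate(LIN, lo) > growth_rate(LIN, hi)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurveSpec("cubic", nu=1e-4, eps=0.05)
        with pytest.raises(ValueError):
            GrowthCurveSpec("gaussian", nu=1e-4, eps=0.05, eta=0.05)
        with pytest.raises(ValueError):
            GrowthCurveSpec("linear", nu=0.0, eps=0.05)


class TestIntegrateElements:
    def test_floor_crossing_up_creates_vacancy(self):
        # linear curve at ca=0 grows exactly nu*dt = 0.2
        curve = GrowthCurveSpec("linear", nu=0.02, eps=0.05)
        pool = ElementPool("Axon_ex", z=2.9, connected=0)
        pool, n_new, n_del = integrate_elements(pool, curve, 0.0, 10.0, CAL)
        assert pool.z == pytest.approx(3.1)
        assert (n_new, n_del) == (1, 0)

    def test_floor_crossing_down_forces_deletion(self):
        # gaussian far above eps retracts at -nu -> dz = -0.1
        curve = GrowthCurveSpec("gaussian", nu=0.01, eps=0.05)
        pool = ElementPool("Den_ex", z=3.05, connected=3)
        pool, n_new, n_del = integrate_elements(pool, curve, 50 * curve.eps, 10.0, CAL)
        assert pool.z == pytest.approx(2.95, abs=1e-6)
        assert (n_new, n_del) == (0, 1)

    def test_negative_z_persists_and_vacancy_clamps(self):
        curve = GrowthCurveSpec("gaussian", nu=0.07, eps=0.05)
        pool = ElementPool("Axon_ex", z=0.5, connected=0)
        pool, n_new, n_del = integrate_elements(pool, curve, 50 * curve.eps, 10.0, CAL)
        assert pool.z == pytest.approx(-0.2, abs=1e-6)
        assert (n_new, n_del) == (0, 0)
        assert pool.vacant == 0

    def test_setpoint_is_fixed_point_for_both_kinds(self):
        for curve in (LIN, GAU):
            pool = ElementPool("Axon_ex", z=5.0, connected=2)
            # hold calcium exactly at eps with no decay over the interval:
            # use a huge tau so ca stays at eps for the linear exact form
            cal = CalciumParams(tau=1e12, beta=0.001)
            pool2, n_new, n_del = integrate_elements(pool, curve, curve.eps, 10.0, cal)
            assert pool2.z == pytest.approx(5.0, abs=1e-9)
            assert (n_new, n_del) == (0, 0)

    def test_linear_exact_matches_fine_euler_under_decaying_calcium(self):
        curve = GrowthCurveSpec("linear", nu=1e-3, eps=0.05)
        ca0, dt = 0.08, 100.0
        z_euler, fine = 0.0, 0.001
        for k in range(int(dt / fine)):
            ca = ca0 * math.exp(-k * fine / CAL.tau)
            z_euler += curve.nu * (1 - ca / curve.eps) * fine
        pool, _, _ = integrate_elements(ElementPool("A", z=0.0), curve, ca0, dt, CAL)
        assert pool.z == pytest.approx(z_euler, rel=1e-4)

    def test_gaussian_is_single_forward_euler_step(self):
        pool, _, _ = integrate_elements(ElementPool("A", z=1.0), GAU, 0.01, 10.0, CAL)
        assert pool.z == pytest.approx(1.0 + growth_rate(GAU, 0.01) * 10.0)


class TestPruneVacant:
    def test_zero_fraction_is_identity(self):
        pool = ElementPool("A", z=12.0, connected=2)
        assert prune_vacant(pool, 0.0).z == 12.0

    def test_full_pruning_leaves_only_connected(self):
        pool = prune_vacant(ElementPool("A", z=5.0, connected=3), 1.0)
        assert pool.z == pytest.approx(3.0)

    def test_fractional_pruning(self):
        pool = prune_vacant(ElementPool("A", z=5.0, connected=3), 0.1)
        assert pool.z == pytest.approx(4.8)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            prune_vacant(ElementPool("A", z=5.0), 1.5)
        with pytest.raises(ValueError):
            prune_vacant(ElementPool("A", z=5.0), -0.1)

    def test_pruning_never_drops_available_below_connected(self):
        pool = ElementPool("A", z=7.9, connected=6)
        for frac in (0.1, 0.5, 1.0):
            assert math.floor(max(prune_vacant(pool, frac).z, 0.0)) >= 6


class TestElementArray:
    def test_vectorized_integrate_matches_scalar(self):
        curves = [
            GrowthCurveSpec("gaussian", nu=2e-3, eps=0.05),
            GrowthCurveSpec("linear", nu=1e-3, eps=0.2),
        ]
        arr = ElementArray("A", np.array([4, 9]), curves)
        arr.z = np.array([0.95, 2.5])
        arr.connected = np.array([0, 2])
        ca = np.array([0.01, 0.3])
        tau = np.array([10000.0, 10000.0])
        n_new, n_del = arr.integrate(ca, 10.0, tau)
        for i, curve in enumerate(curves):
            pool = ElementPool("A", z=[0.95, 2.5][i], connected=[0, 2][i])
            pool, s_new, s_del = integrate_elements(pool, curve, ca[i], 10.0, CAL)
            assert arr.z[i] == pytest.approx(pool.z, rel=1e-12)
            assert (n_new[i], n_del[i]) == (s_new, s_del)

    def test_owner_ids_must_increase(self):
        with pytest.raises(ValueError):
            ElementArray("A", np.array([3, 3]), [GAU, GAU])

    def test_index_of_unknown_neuron_raises(self):
        arr = ElementArray("A", np.array([1, 5]), [GAU, GAU])
        with pytest.raises(KeyError):
            arr.index_of(np.array([2]))
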