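"""Operator sub-steps against closed forms and independent ODE oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cruspark.sim import (
    GatingParams,
    SercaParams,
    diffusion_step,
    gating_step,
    reaction_step,
    ryr_rates,
    ryr_release_analytic,
    serca_step,
)
from cruspark.sim.params import default_gating


class TestRates:
    def test_low_ca_hits_lower_clamp(self):
        g = default_gating()
        kp, km = ryr_rates(1e-6, g)
        assert kp == pytest.approx(g.k_min_plus)
        assert km == pytest.approx(g.k_max_minus)  # closing fast at low Ca

    def test_high_ca_hits_upper_clamp(self):
        g = default_gating()
        kp, km = ryr_rates(1e9, g)
        assert kp == pytest.approx(g.k_max_plus)
        assert km == pytest.approx(g.k_min_minus)

    def test_half_maximal_activation_at_80_um(self):
        g = default_gating()
        kp, _ = ryr_rates(80.0, g)
        assert kp == pytest.approx(0.5 * (g.k_min_plus + g.k_max_plus), rel=1e-12)
        assert g.half_activation_um() == pytest.approx(80.0, rel=1e-12)

    def test_opening_rate_monotone_in_ca(self):
        g = default_gating()
        c = np.logspace(-3, 4, 200)
        kp, _ = ryr_rates(c, g)
        assert (np.diff(kp) >= -1e-15).all()


class TestGatingStep:
    def test_zero_opening_rate_keeps_closed(self):
        g = GatingParams(phi_plus=0.0, k_min_plus=0.0, k_max_plus=0.0)
        gamma = np.zeros(50, dtype=np.uint8)
        rng = np.random.default_rng(0)
        for _ in range(100):
            gamma = gating_step(gamma, np.full(50, 10.0), g, 0.01, rng)
        assert (gamma == 0).all()

    def test_stationary_distribution(self):
        """Long-run open fraction at clamped Ca matches k+/(k+ + k-)."""
        g = default_gating()
        c = 50.0
        kp, km = ryr_rates(c, g)
        expect = kp / (kp + km)
        rng = np.random.default_rng(7)
        gamma = np.zeros(200, dtype=np.uint8)
        dt = 0.05
        frac = []
        for step in range(10_000):
            gamma = gating_step(gamma, np.full(200, c), g, dt, rng)
            if step > 500:
                frac.append(gamma.mean())
        got = np.mean(frac)
        # MC error ~ sqrt(p(1-p)/n_eff); generous 3 sigma with correlation
        assert abs(got - expect) < 0.03

    def test_deterministic_given_seed(self):
        g = default_gating()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            gamma = np.zeros(30, dtype=np.uint8)
            traj = []
            for _ in range(200):
                gamma = gating_step(gamma, np.full(30, 100.0), g, 0.01, rng)
                traj.append(gamma.copy())
            out.append(np.array(traj))
        np.testing.assert_array_equal(out[0], out[1])


def _box_mesh(n):
    """Neighbour table for an n^3 all-open box (for diffusion tests)."""
    ids = np.arange(n**3).reshape(n, n, n)
    nbr = -np.ones((n**3, 6), dtype=np.int32)
    for slot, (axis, sign) in enumerate(
        [(0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)]
    ):
        src = np.roll(ids, -sign, axis=axis)
        valid = np.ones((n, n, n), dtype=bool)
        idx = [slice(None)] * 3
        idx[axis] = -1 if sign == 1 else 0
        valid[tuple(idx)] = False
        nbr[ids[valid], slot] = src[valid]
    return nbr


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        nbr = _box_mesh(8)
        f = np.full(512, 3.7)
        out = diffusion_step(f, nbr, np.array([0.1, 0.1, 0.1]))
        np.testing.assert_allclose(out, f, rtol=1e-14)

    def test_amount_conserved(self, rng):
        nbr = _box_mesh(10)
        f = rng.random(1000) * 10
        total = f.sum()
        for _ in range(50):
            f = diffusion_step(f, nbr, np.array([0.1, 0.08, 0.12]))
        assert f.sum() == pytest.approx(total, rel=1e-12)

    def test_point_release_matches_gaussian_kernel(self):
        """Free diffusion of a point mass matches the analytic 3D kernel."""
        n = 33
        h = 0.012
        d_c = 0.22
        dt = 1e-4
        nbr = _box_mesh(n)
        f = np.zeros(n**3)
        mid = (n // 2) * n * n + (n // 2) * n + (n // 2)
        f[mid] = 1.0
        steps = 100
        alpha = np.full(3, d_c * dt / h**2)
        for _ in range(steps):
            f = diffusion_step(f, nbr, alpha)
        t = steps * dt
        xs = (np.arange(n) - n // 2) * h
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        r2 = gx**2 + gy**2 + gz**2
        analytic = np.exp(-r2 / (4 * d_c * t)) / (4 * np.pi * d_c * t) ** 1.5
        analytic *= h**3  # per-voxel mass
        got = f.reshape(n, n, n)
        core = r2 < (3 * np.sqrt(2 * d_c * t)) ** 2
        rel = np.abs(got[core] - analytic[core]) / analytic[core].max()
        assert rel.max() < 0.02


class TestReaction:
    B, KON, KOFF = 50.0, 0.1, 0.09

    def test_equilibrium_fixed_point(self):
        c = np.array([0.5])
        b_eq = self.B * 0.5 / (0.5 + self.KOFF / self.KON)
        c2, b2 = reaction_step(c, np.array([b_eq]), self.B, self.KON, self.KOFF, 1e-3)
        assert c2[0] == pytest.approx(0.5, rel=1e-12)
        assert b2[0] == pytest.approx(b_eq, rel=1e-12)

    def test_relaxation_matches_ode_oracle(self):
        # fixed free Ca (clamped analytically): db/dt = kon*c*(B-b) - koff*b
        c0 = 2.0
        dt = 2e-6  # small enough that forward-Euler error < 1e-6
        b = np.array([0.0])
        for _ in range(250_000):
            # re-clamp c so the scalar ODE applies
            _, b = reaction_step(np.array([c0]), b, self.B, self.KON, self.KOFF, dt)
        sol = solve_ivp(
            lambda t, y: self.KON * c0 * (self.B - y) - self.KOFF * y,
            (0, 0.5), [0.0], rtol=1e-10, atol=1e-12,
        )
        assert b[0] == pytest.approx(sol.y[0, -1], rel=1e-6)

    def test_zero_rates_identity(self):
        c = np.array([1.0, 2.0])
        b = np.array([3.0, 4.0])
        c2, b2 = reaction_step(c, b, 50.0, 0.0, 0.0, 1.0)
        np.testing.assert_array_equal(c2, c)
        np.testing.assert_array_equal(b2, b)

    def test_sum_invariant(self, rng):
        c = rng.random(100)
        b = rng.random(100) * 10
        c2, b2 = reaction_step(c, b, self.B, self.KON, self.KOFF, 1e-3)
        np.testing.assert_allclose(c2 + b2, c + b, rtol=1e-13)


class TestSerca:
    def test_zero_flux_at_balance(self):
        p = SercaParams(a1=1.0, a2=4.0, a3=1.0, a4=1.0, a5=0.1)
        # a1 c^2 = a2 s^2 -> c = 2 s
        assert p.flux(2.0, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_forward_uptake_sign(self):
        p = SercaParams()
        assert p.flux(10.0, 100.0) > 0

    def test_matches_hand_computed_expression(self):
        p = SercaParams(a1=2.0, a2=3.0, a3=0.5, a4=0.25, a5=1.5)
        c, s = 1.7, 3.1
        expect = (2.0 * c**2 - 3.0 * s**2) / (0.5 * c**2 + 0.25 * s**2 + 1.5)
        assert p.flux(c, s) == pytest.approx(expect, rel=1e-14)

    def test_step_conserves_calcium(self):
        p = SercaParams()
        c = np.array([5.0, 5.0])
        s = np.array([100.0])
        vol = 1.728e-6
        c2, s2 = serca_step(
            c, s, np.array([0, 1]), np.array([0, 0]),
            np.full(2, 1.44e-4), vol, p, 1e-4,
        )
        assert (c2.sum() + s2.sum()) == pytest.approx(c.sum() + s.sum(), rel=1e-12)


class TestReleaseAnalytic:
    def test_dt_zero_identity(self):
        x, y = ryr_release_analytic(1000.0, 0.1, 5.0, 0.0)
        assert x == pytest.approx(1000.0, abs=1e-10)
        assert y == pytest.approx(0.1, abs=1e-10)

    def test_infinite_time_equilibrates(self):
        x, y = ryr_release_analytic(1000.0, 0.1, 5.0, 1e9)
        assert x == pytest.approx(500.05)
        assert y == pytest.approx(500.05)

    def test_matches_adaptive_ode_oracle(self):
        x0, y0, k, dt = 1000.0, 0.1, 5.0, 0.01
        sol = solve_ivp(
            lambda t, v: [k * (v[1] - v[0]), k * (v[0] - v[1])],
            (0, dt), [x0, y0], rtol=1e-12, atol=1e-12,
        )
        x, y = ryr_release_analytic(x0, y0, k, dt)
        assert x == pytest.approx(sol.y[0, -1], abs=1e-10)
        assert y == pytest.approx(sol.y[1, -1], abs=1e-10)

    def test_sum_invariant_any_dt(self, rng):
        for _ in range(20):
            x0, y0 = rng.random(2) * 1000
            k = rng.random() * 100
            dt = rng.random() * 10
            x, y = ryr_release_analytic(x0, y0, k, dt)
            assert x + y == pytest.approx(x0 + y0, rel=1e-12)
            # unconditionally stable: stays within [min, max]
            assert min(x0, y0) - 1e-9 <= x <= max(x0, y0) + 1e-9
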