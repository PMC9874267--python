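"""Resident ecological model: ODEs, equilibria, R0 and their cross-checks."""

import numpy as np
import pytest

from stageres import (
    Params,
    ResistancePair,
    TradeoffWiring,
    basic_reproduction_number,
    disease_free_equilibrium,
    effective_rates,
    endemic_equilibria,
    endemic_equilibrium,
    integrate_dynamics,
    ngm_r0_numeric,
    ode_rhs,
)
from stageres.ecology import ode_jacobian

from .conftest import draw_viable_setup

NO_RESIST = ResistancePair(0.0, 0.0)


class TestOdeRhs:
    def test_extinction_is_an_equilibrium(self, default_wiring):
        p = Params(beta0=8.0)
        rates = effective_rates(p, default_wiring, NO_RESIST)
        assert np.allclose(ode_rhs(np.zeros(4), rates, p), 0.0)

    def test_disease_free_closed_form_is_a_fixed_point(self, default_wiring):
        p = Params(beta0=8.0)
        dfe = disease_free_equilibrium(p, default_wiring, NO_RESIST)
        rates = effective_rates(p, default_wiring, NO_RESIST)
        assert np.max(np.abs(ode_rhs(dfe.state.as_array(), rates, p))) < 1e-10

    def test_hand_evaluated_derivatives(self, default_wiring):
        # SJ=SA=0.2, IJ=IA=0.1, defaults with beta0=8, f=1, alpha=0, r=0:
        # N=0.6, I=0.2, lambda=1.6 at both stages, so
        # dSJ = 5*0.4*0.3 - 3.6*0.2 = -0.12;  dSA = 0.2 - 2.6*0.2 = -0.32
        # dIJ = 1.6*0.2 - 2*0.1 = 0.12;       dIA = 0.1 + 1.6*0.2 - 0.1 = 0.32
        p = Params(beta0=8.0, f=1.0, alpha=0.0)
        rates = effective_rates(p, default_wiring, NO_RESIST)
        dy = ode_rhs(np.array([0.2, 0.2, 0.1, 0.1]), rates, p)
        assert dy == pytest.approx([-0.12, -0.32, 0.12, 0.32], abs=1e-14)

    def test_negative_densities_rejected(self, default_wiring):
        p = Params()
        rates = effective_rates(p, default_wiring, NO_RESIST)
        with pytest.raises(ValueError):
            ode_rhs(np.array([-0.1, 0.2, 0.1, 0.1]), rates, p)

    def test_analytic_jacobian_matches_finite_differences(self, default_wiring):
        p = Params(beta0=8.0, f=0.3, alpha=0.5)
        rates = effective_rates(p, default_wiring, ResistancePair(0.2, 0.4))
        y = np.array([0.15, 0.22, 0.08, 0.11])
        J = ode_jacobian(y, rates, p)
        h = 1e-7
        for j in range(4):
            up, dn = y.copy(), y.copy()
            up[j] += h
            dn[j] -= h
            col = (ode_rhs(up, rates, p) - ode_rhs(dn, rates, p)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-6)


class TestDiseaseFreeEquilibrium:
    def test_default_values(self, default_wiring):
        # a=5, g=1, bJ=bA=1: S_J* = S_A* = 0.3
        dfe = disease_free_equilibrium(Params(), default_wiring, NO_RESIST)
        assert dfe.state.SJ == pytest.approx(0.3, abs=1e-12)
        assert dfe.state.SA == pytest.approx(0.3, abs=1e-12)
        assert dfe.kind == "disease_free"

    def test_marginal_viability_returns_extinct(self, default_wiring):
        # a g = bA (bJ + g) exactly: a0=2, g=1, b=1
        dfe = disease_free_equilibrium(Params(a0=2.0), default_wiring, NO_RESIST)
        assert dfe.kind == "extinct"
        assert dfe.state.N == 0.0

    def test_nonviable_host_extinct(self, default_wiring):
        dfe = disease_free_equilibrium(Params(a0=1.0), default_wiring, NO_RESIST)
        assert dfe.kind == "extinct"

    def test_matches_time_integration_over_random_draws(self):
        """Closed form agrees with the ODE steady state, including under
        asymmetric stage mortality from trade-offs."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            p, w, r = draw_viable_setup(rng)
            p = p.replace(beta0=0.0)
            dfe = disease_free_equilibrium(p, w, r)
            if dfe.kind == "extinct":
                continue
            y = integrate_dynamics(
                p, w, r, [0.2, 0.2, 0.0, 0.0], t_max=4000.0, steady_tol=1e-11
            )
            assert np.max(np.abs(dfe.state.as_array() - y)) < 1e-6


class TestBasicReproductionNumber:
    def test_reference_value(self, default_wiring):
        assert basic_reproduction_number(
            Params(beta0=8.0, alpha=0.0), default_wiring, NO_RESIST
        ) == pytest.approx(4.8, abs=1e-12)

    def test_zero_at_full_resistance(self, default_wiring):
        # weak costs keep the host viable at (1, 1); both transmission
        # terms still vanish, so no secondary infections at all
        assert basic_reproduction_number(
            Params(beta0=8.0, c1J=0.2, c1A=0.2), default_wiring, ResistancePair(1.0, 1.0)
        ) == pytest.approx(0.0, abs=1e-14)

    def test_linear_in_transmissibility(self, default_wiring):
        r = ResistancePair(0.3, 0.1)
        base = basic_reproduction_number(Params(beta0=2.0), default_wiring, r)
        assert basic_reproduction_number(
            Params(beta0=7.0), default_wiring, r
        ) == pytest.approx(3.5 * base, rel=1e-12)

    def test_nonviable_host_rejected(self, default_wiring):
        with pytest.raises(ValueError):
            basic_reproduction_number(Params(a0=1.0), default_wiring, NO_RESIST)

    def test_matches_next_generation_matrix(self):
        """Closed form equals the spectral radius of the numerically
        assembled next-generation matrix across random draws."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            p, w, r = draw_viable_setup(rng)
            closed = basic_reproduction_number(p, w, r)
            numeric = ngm_r0_numeric(p, w, r)
            assert closed == pytest.approx(numeric, rel=1e-8, abs=1e-10)

    def test_nonincreasing_in_resistance(self, default_wiring):
        p = Params(beta0=8.0, alpha=0.5, f=1.0)
        grid = np.linspace(0.0, 1.0, 11)
        valsJ = [basic_reproduction_number(p, default_wiring, ResistancePair(r, 0.2)) for r in grid]
        valsA = [basic_reproduction_number(p, default_wiring, ResistancePair(0.2, r)) for r in grid]
        assert np.all(np.diff(valsJ) < 0)
        assert np.all(np.diff(valsA) < 0)


class TestEndemicEquilibrium:
    def test_below_threshold_returns_disease_free(self, default_wiring):
        eq = endemic_equilibrium(Params(beta0=0.1), default_wiring, NO_RESIST)
        assert eq.kind == "disease_free"

    def test_endemic_state_properties(self, default_wiring):
        p = Params(beta0=8.0, f=0.1, alpha=0.0)
        eq = endemic_equilibrium(p, default_wiring, NO_RESIST)
        assert eq.kind == "endemic"
        assert eq.state.infected > 0
        assert eq.residual < 1e-9
        assert eq.stable
        assert all(ev.real < 0 for ev in eq.eigenvalues)

    def test_matches_long_time_integration(self, default_wiring):
        p = Params(beta0=8.0, f=0.1, alpha=0.0)
        eq = endemic_equilibrium(p, default_wiring, NO_RESIST)
        y = integrate_dynamics(
            p, default_wiring, NO_RESIST, [0.1] * 4, t_max=5000.0, steady_tol=1e-11
        )
        assert np.max(np.abs(eq.state.as_array() - y)) < 1e-8

    def test_infected_density_vanishes_at_threshold(self, default_wiring):
        """Continuity: the endemic branch shrinks to zero as beta0 drops
        to the critical value where R0 = 1 (beta0 = 5/3 at defaults)."""
        beta_crit = 5.0 / 3.0
        last = np.inf
        for eps in (1e-1, 1e-2, 1e-3, 1e-4):
            eq = endemic_equilibrium(
                Params(beta0=beta_crit * (1 + eps), f=1.0), default_wiring, NO_RESIST
            )
            assert eq.kind == "endemic"
            assert eq.state.infected < last
            last = eq.state.infected
        assert last < 1e-3

    def test_unique_endemic_root_at_showcase_parameters(self, default_wiring):
        roots = endemic_equilibria(
            Params(beta0=8.0, f=0.1, alpha=0.0), default_wiring, NO_RESIST
        )
        assert len(roots) == 1 and roots[0].stable

    def test_nondimensional_rescaling_reproduces_solutions(self, default_wiring):
        """Solving with (q, b0) = (1, 1) and rescaling densities by 1/q
        reproduces the equilibrium for arbitrary (q, b0)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            q = float(rng.uniform(0.2, 4.0))
            b0 = float(rng.uniform(0.4, 2.5))
            a, g, f, beta = 6.0, 1.2, float(rng.uniform(0.0, 0.8)), 9.0
            p_orig = Params(a0=a * b0, g0=g * b0, b0=b0, q=q, beta0=beta * q * b0, f=f)
            p_unit = Params(a0=a, g0=g, b0=1.0, q=1.0, beta0=beta, f=f)
            r = ResistancePair(float(rng.uniform(0, 0.6)), float(rng.uniform(0, 0.6)))
            e1 = endemic_equilibrium(p_orig, default_wiring, r)
            e2 = endemic_equilibrium(p_unit, default_wiring, r)
            assert e1.kind == e2.kind
            assert np.max(np.abs(e1.state.as_array() - e2.state.as_array() / q)) < 1e-9
            assert basic_reproduction_number(
                p_orig, default_wiring, r
            ) == pytest.approx(basic_reproduction_number(p_unit, default_wiring, r), rel=1e-12)

    def test_random_draws_residual_and_stability_consistency(self):
        """Every reported equilibrium satisfies the residual bound and the
        stability flag matches the Jacobian eigenvalue test."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            p, w, r = draw_viable_setup(rng)
            eq = endemic_equilibrium(p, w, r)
            assert eq.residual < 1e-9
            if eq.eigenvalues:
                assert eq.stable == all(ev.real < 0 for ev in eq.eigenvalues)
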