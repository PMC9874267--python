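"""Invasion fitness, selection gradients and singular-strategy machinery."""

import numpy as np
import pytest

from stageres import (
    ALL_WIRINGS,
    MutantTrait,
    Params,
    ResistancePair,
    TradeoffWiring,
    convergence_stability,
    evolutionary_stability,
    find_cosingular,
    invasion_fitness,
    resident_context,
    selection_gradient_map,
    selection_gradients,
)

from .conftest import draw_endemic_setup
from .oracles import mutant_growth_rate


class TestInvasionFitness:
    def test_resident_is_neutral_in_its_own_environment(self):
        """w_i(mutant = resident) = 0 to 1e-10 across random draws — the
        central correctness anchor of the fitness expression."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            p, w, r = draw_endemic_setup(rng)
            ctx = resident_context(p, w, r, require_endemic=True)
            for stage, v in (("juvenile", r.rJ), ("adult", r.rA)):
                assert abs(invasion_fitness(ctx, MutantTrait(stage, v), p, w)) < 1e-10

    def test_sign_matches_linearized_growth_rate(self):
        """Fitness sign agrees with the dominant eigenvalue of the mutant's
        linearized invasion dynamics (independent oracle)."""
        rng = np.random.default_rng(29)
        for _ in range(50):
            p, w, r = draw_endemic_setup(rng)
            ctx = resident_context(p, w, r, require_endemic=True)
            stage = "juvenile" if rng.random() < 0.5 else "adult"
            value = float(rng.uniform(0.0, 1.0))
            fit = invasion_fitness(ctx, MutantTrait(stage, value), p, w)
            lam = mutant_growth_rate(p, w, ctx, stage, value)
            if abs(fit) > 1e-6:
                assert np.sign(fit) == np.sign(lam)

    def test_juvenile_resistance_invades_susceptible_resident(self, css_params, default_wiring):
        """At the single-CSS showcase parameters a small increase of
        juvenile resistance from zero is favoured."""
        ctx = resident_context(css_params, default_wiring, ResistancePair(0.0, 0.0))
        fit = invasion_fitness(ctx, MutantTrait("juvenile", 0.02), css_params, default_wiring)
        assert fit > 0
        assert mutant_growth_rate(css_params, default_wiring, ctx, "juvenile", 0.02) > 0

    def test_requires_endemic_resident(self, default_wiring):
        p = Params(beta0=0.5)  # R0 < 1: disease cannot persist
        ctx = resident_context(p, default_wiring, ResistancePair(0.0, 0.0))
        with pytest.raises(ValueError):
            invasion_fitness(ctx, MutantTrait("adult", 0.1), p, default_wiring)
        # the cost-only fitness is still defined (and resident-neutral) on request
        assert invasion_fitness(
            ctx, MutantTrait("adult", 0.0), p, default_wiring, allow_disease_free=True
        ) == pytest.approx(0.0, abs=1e-12)


class TestSelectionGradients:
    def test_vanish_at_cosingular_point(self, css_params, default_wiring):
        pts = [q for q in find_cosingular(css_params, default_wiring) if not q.boundary]
        assert len(pts) == 1
        ctx = resident_context(css_params, default_wiring, pts[0].traits)
        assert np.max(np.abs(selection_gradients(ctx, css_params, default_wiring))) < 1e-7

    def test_positive_without_tradeoffs(self, default_wiring):
        """Costless resistance is always favoured while disease is endemic."""
        p = Params(beta0=8.0, f=0.1, alpha=0.0, c1J=0.0, c1A=0.0)
        for r in (ResistancePair(0.1, 0.1), ResistancePair(0.5, 0.5), ResistancePair(0.8, 0.3)):
            ctx = resident_context(p, default_wiring, r)
            assert np.all(selection_gradients(ctx, p, default_wiring) > 0)

    def test_nonpositive_without_any_virulence(self, default_wiring):
        """With f=1 and alpha=0 infection is harmless, so costly resistance
        can only be selected against."""
        p = Params(beta0=8.0, f=1.0, alpha=0.0)
        for r in (ResistancePair(0.2, 0.2), ResistancePair(0.5, 0.7)):
            ctx = resident_context(p, default_wiring, r)
            assert np.all(selection_gradients(ctx, p, default_wiring) <= 0)


class TestStabilityClassifiers:
    def test_injected_quadratic_fitness_curvature(self):
        """A synthetic fitness with known curvature per stage classifies by
        the sign of its analytic second derivative."""
        point = (0.4, 0.6)

        def fitness(stage, value):
            if stage == "juvenile":
                return -(value - point[0]) ** 2  # concave: ES
            return +(value - point[1]) ** 2  # convex: invadable

        es_J, es_A = evolutionary_stability(
            point, Params(), TradeoffWiring(), fitness=fitness
        )
        assert es_J is True and es_A is False

    def test_injected_linear_gradient_fields(self):
        p, w = Params(), TradeoffWiring()
        contracting = lambda rJ, rA: np.array([-(rJ - 0.5), -(rA - 0.5)])
        strong, J, eig = convergence_stability((0.5, 0.5), p, w, gradient_map=contracting)
        assert strong is True and np.all(np.real(eig) < 0)
        expanding = lambda rJ, rA: np.array([rJ - 0.5, rA - 0.5])
        strong, J, eig = convergence_stability((0.5, 0.5), p, w, gradient_map=expanding)
        assert strong is False and np.all(np.real(eig) > 0)

    def test_near_flat_field_flagged_indeterminate(self):
        flat = lambda rJ, rA: np.zeros(2)
        strong, _, _ = convergence_stability((0.5, 0.5), Params(), TradeoffWiring(), gradient_map=flat)
        assert strong is None


class TestFindCosingular:
    def test_single_css_at_showcase_parameters(self, css_params, default_wiring):
        pts = find_cosingular(css_params, default_wiring)
        attractors = [q for q in pts if q.is_attractor]
        assert len(attractors) == 1
        css = attractors[0]
        assert css.classification == "CSS"
        assert css.es_J and css.es_A and css.convergent and css.strongly_convergent
        assert 0.0 < css.rJ < 1.0 and 0.0 < css.rA < 1.0

    def test_classification_stable_under_halved_steps(self, css_params, default_wiring):
        """Halving the finite-difference steps does not change the CSS
        classification or move the singular point."""
        css = [q for q in find_cosingular(css_params, default_wiring) if q.is_attractor][0]
        es = evolutionary_stability(css, css_params, default_wiring, h=5e-5)
        assert es == (True, True)
        strong, _, eig = convergence_stability(css, css_params, default_wiring, h=5e-5)
        assert strong is True and np.all(np.real(eig) < 0)

    def test_bistable_parameters_yield_two_attractors(self, bistable_setup):
        p, w = bistable_setup
        pts = find_cosingular(p, w)
        attractors = [q for q in pts if q.is_attractor]
        assert len(attractors) == 2
        high = max(attractors, key=lambda q: q.rJ + q.rA)
        low = min(attractors, key=lambda q: q.rJ + q.rA)
        assert high.rJ > 0.9 and high.rA > 0.9
        assert low.rJ == 0.0 and low.rA == 0.0

    def test_no_virulence_gives_zero_resistance_attractor(self):
        p = Params(beta0=8.0, f=1.0, alpha=0.0)
        for w in ALL_WIRINGS[:3]:
            attractors = [q for q in find_cosingular(p, w) if q.is_attractor]
            assert len(attractors) == 1
            assert (attractors[0].rJ, attractors[0].rA) == (0.0, 0.0)

    def test_gradient_map_points_downcost_outside_viability(self, default_wiring):
        # (1, 1) under this wiring is exactly marginal: no selection defined,
        # the map returns a descent direction back into the viable region
        G = selection_gradient_map(Params(beta0=8.0), default_wiring)
        assert np.all(G(1.0, 1.0) < 0)
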