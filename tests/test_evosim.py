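"""Trait-substitution simulation: ecological consistency, determinism and
distribution summaries."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stageres import (
    Params,
    ResistancePair,
    TraitGrid,
    TradeoffWiring,
    endemic_equilibrium,
    simulate_evolution,
    trait_distribution_summary,
)
from stageres.evosim import _multi_rhs, _rates_arrays


class TestTraitGrid:
    def test_default_grid_has_51_phenotypes(self):
        grid = TraitGrid()
        assert grid.n == 51
        assert grid.value(0) == 0.0 and grid.value(50) == 1.0

    def test_index_value_roundtrip(self):
        grid = TraitGrid(0.05)
        for i in range(grid.n):
            assert grid.index(grid.value(i)) == i

    def test_step_must_divide_unit_interval(self):
        with pytest.raises(ValueError):
            TraitGrid(0.03)


class TestMultiPhenotypeEcology:
    def test_single_phenotype_reduction_matches_resident_equilibrium(self):
        """Restricted to one phenotype (mutation disabled), the shared-arena
        integrator settles on the same endemic equilibrium as the resident
        ecological solver."""
        p = Params(beta0=8.0, f=0.1, alpha=0.0)
        w = TradeoffWiring("juvenile_mortality", "reproduction")
        grid = TraitGrid()
        r = ResistancePair(0.3, 0.2)
        rates = _rates_arrays(p, w, [(grid.index(0.3), grid.index(0.2))], grid)
        sol = solve_ivp(
            _multi_rhs, (0.0, 4000.0), np.full(4, 0.1), args=(rates, p),
            method="LSODA", rtol=1e-12, atol=1e-14,
        )
        expected = endemic_equilibrium(p, w, r).state.as_array()
        assert np.max(np.abs(sol.y[:, -1] - expected)) < 1e-8


@pytest.fixture(scope="module")
def short_run():
    p = Params(beta0=8.0, f=0.1, alpha=0.0)
    w = TradeoffWiring("juvenile_mortality", "reproduction")
    return simulate_evolution(p, w, ResistancePair(0.2, 0.2), n_events=120, seed=42)


class TestSimulateEvolution:

    def test_deterministic_given_seed(self, short_run):
        p = Params(beta0=8.0, f=0.1, alpha=0.0)
        w = TradeoffWiring("juvenile_mortality", "reproduction")
        again = simulate_evolution(p, w, ResistancePair(0.2, 0.2), n_events=120, seed=42)
        assert again.trajectory.equals(short_run.trajectory)
        other = simulate_evolution(p, w, ResistancePair(0.2, 0.2), n_events=120, seed=43)
        assert not other.trajectory.equals(short_run.trajectory)

    def test_monomorphic_start_has_zero_variance(self, short_run):
        first = short_run.trajectory.iloc[0]
        assert first["rJ_var"] == 0.0 and first["rA_var"] == 0.0

    def test_traits_move_towards_higher_resistance(self, short_run):
        """From (0.2, 0.2) with strong sterility virulence both resistance
        traits are under positive selection initially."""
        assert short_run.final.rJ > 0.2
        assert short_run.final.rA > 0.2
        assert not short_run.extinct

    def test_means_stay_in_unit_square(self, short_run):
        t = short_run.trajectory
        assert ((t["rJ_mean"] >= 0) & (t["rJ_mean"] <= 1)).all()
        assert ((t["rA_mean"] >= 0) & (t["rA_mean"] <= 1)).all()

    def test_summary_statistics(self, short_run):
        summ = trait_distribution_summary(short_run)
        assert len(summ) == len(short_run.trajectory)
        assert np.allclose(summ["rJ_mean"], short_run.trajectory["rJ_mean"])
        # a single quasi-monomorphic cloud: never two well-separated modes
        assert not summ.attrs["rJ_sustained_bimodality"]
        assert not summ.attrs["rA_sustained_bimodality"]

    def test_rejects_nonviable_start(self):
        with pytest.raises(ValueError):
            simulate_evolution(
                Params(a0=1.0), TradeoffWiring(), ResistancePair(0.0, 0.0), n_events=5
            )

    def test_rejects_zero_events(self):
        with pytest.raises(ValueError):
            simulate_evolution(
                Params(), TradeoffWiring(), ResistancePair(0.0, 0.0), n_events=0
            )
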