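"""Individual-based dynamics: growth, division, sharing, motion."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from rspm.connectivity import compute_hydration_state
from rspm.ibm import (
    Population,
    SpeciesParams,
    SpeciesTable,
    divide_or_die,
    grow_and_consume,
    move_cells,
    nutrient_sharing_factor,
    specific_growth_rate,
    step_probabilities,
)
from rspm.motility import DEFAULT_FORCE_MODEL, ForceModel
from rspm.surface import RoughnessParams, effective_film_thickness
from rspm.transport import NutrientField, NutrientSpec

from conftest import uniform_patch_grid

MODEL = DEFAULT_FORCE_MODEL


def simple_species(**kw):
    defaults = dict(
        name="sp",
        mu_max=1.0 / 3600.0,
        k_s={"glucose": 1e-3},
        y_max={"glucose": 0.5},
        alpha_m=0.0,
    )
    defaults.update(kw)
    return SpeciesParams(**defaults)


def setup_world(n=8, phi=0.9, psi=-500.0, boundary="closed", c0=1e-3, species=None):
    grid = uniform_patch_grid(n=n, phi=phi)
    state = compute_hydration_state(grid, psi, MODEL)
    field = NutrientField(
        grid, state, [NutrientSpec("glucose", c0=c0, boundary=boundary)]
    )
    species = species or [simple_species()]
    table = SpeciesTable(species, field.names)
    return grid, state, field, table


# ----------------------------------------------------------------------
class TestSpecificGrowthRate:
    def test_half_saturation(self):
        sp = simple_species(alpha_m=0.1)
        mu, _ = specific_growth_rate(sp, {"glucose": 1e-3})
        assert mu == pytest.approx(sp.mu_max / 2)

    def test_min_law_two_nutrients(self):
        sp = simple_species(
            k_s={"a": 1e-3, "b": 1e-3}, y_max={"a": 0.5, "b": 0.5}
        )
        mu, _ = specific_growth_rate(sp, {"a": 1.0, "b": 1e-3})
        assert mu == pytest.approx(sp.mu_max / 2)  # limited by b

    def test_pure_maintenance_decay_at_zero_substrate(self):
        sp = simple_species(alpha_m=0.2)
        mu, mu_t = specific_growth_rate(sp, {"glucose": 0.0})
        assert mu == 0.0
        assert mu_t == pytest.approx(-0.2 * sp.mu_max)


class TestNutrientSharing:
    def test_unity_at_full_connectivity(self):
        rng = np.random.default_rng(0)
        f = nutrient_sharing_factor(np.ones(100), rng)
        assert np.all(f == 1.0)

    def test_uniform_at_zero_connectivity(self):
        rng = np.random.default_rng(1)
        f = nutrient_sharing_factor(np.zeros(10_000), rng)
        assert kstest(f, "uniform").pvalue > 0.01

    def test_mean_at_half_connectivity(self):
        rng = np.random.default_rng(2)
        f = nutrient_sharing_factor(np.full(10_000, 0.5), rng)
        assert abs(f.mean() - 0.75) <= 0.01  # E[f_p] = (1+xi)/2


# ----------------------------------------------------------------------
class TestGrowAndConsume:
    def test_no_cells_no_uptake(self):
        grid, state, field, table = setup_world()
        pop = Population([], [], [])
        realised = grow_and_consume(pop, table, field, state.xi, 60.0, np.random.default_rng(0))
        assert np.all(realised == 0)

    def test_single_cell_matches_ode_oracle(self):
        """One cell at xi=1 in a closed patch follows the coupled (b, C)
        Monod system to 0.5% at dt = 1 s."""
        grid, state, field, table = setup_world(phi=0.9, psi=-500.0)
        xi = np.ones(grid.n_patches)  # fully connected: f_p = 1
        pop = Population([0], [1.5e-16], [9])
        sp = table.species[0]
        v_w = field.V_w[9]

        def rhs(t, y):
            b, c = y
            mu = sp.mu_max * c / (1e-3 + c)
            return [mu * b, -mu * b / (0.5 * v_w)]

        t_end = 6 * 3600.0
        sol = solve_ivp(
            rhs, (0, t_end), [1.5e-16, 1e-3], rtol=1e-10, atol=1e-22
        )
        rng = np.random.default_rng(3)
        for _ in range(int(t_end)):
            grow_and_consume(pop, table, field, xi, 1.0, rng)
        assert pop.biomass[0] == pytest.approx(sol.y[0, -1], rel=5e-3)
        assert field.C[9, 0] == pytest.approx(sol.y[1, -1], rel=5e-3)

    def test_yield_bookkeeping(self):
        """Consumed substrate mass times Y_max equals gross growth mass when
        f_p = 1 and maintenance = 0."""
        grid, state, field, table = setup_world()
        xi = np.ones(grid.n_patches)
        pop = Population([0, 0, 0], [2e-16, 3e-16, 1.5e-16], [5, 5, 12])
        b0 = pop.biomass.sum()
        realised = grow_and_consume(
            pop, table, field, xi, 30.0, np.random.default_rng(0)
        )
        growth = pop.biomass.sum() - b0
        assert growth == pytest.approx(0.5 * realised.sum(), rel=1e-9)

    def test_starvation_clock_and_reset(self):
        grid, state, field, table = setup_world(
            species=[simple_species(alpha_m=0.1)]
        )
        xi = np.ones(grid.n_patches)
        pop = Population([0], [1.5e-16], [0])
        rng = np.random.default_rng(0)
        field.C[:] = 0.0
        grow_and_consume(pop, table, field, xi, 100.0, rng)
        assert pop.starvation[0] == 100.0
        field.C[:] = 1.0  # saturating again
        grow_and_consume(pop, table, field, xi, 100.0, rng)
        assert pop.starvation[0] == 0.0


class TestDivisionAndDeath:
    def test_division_conserves_biomass(self):
        grid, state, field, table = setup_world()
        pop = Population([0, 0], [3.0e-16, 2.0e-16], [1, 2])
        total = pop.biomass.sum()
        divide_or_die(pop, table)
        assert len(pop) == 3  # one division
        assert pop.biomass.sum() == pytest.approx(total)
        daughters = pop.biomass[pop.patch == 1]
        assert np.allclose(daughters, 1.5e-16)

    def test_survives_below_threshold(self):
        grid, state, field, table = setup_world()
        pop = Population([0], [1.5e-16], [0])
        pop.starvation[0] = table.death_time[0] - 1.0
        divide_or_die(pop, table)
        assert len(pop) == 1

    def test_death_at_clock_threshold(self):
        """Sustained starvation kills the cell once the clock passes the
        species threshold (within one step)."""
        grid, state, field, table = setup_world(
            species=[simple_species(alpha_m=0.1, starvation_death_time=600.0)]
        )
        xi = np.ones(grid.n_patches)
        field.C[:] = 0.0
        pop = Population([0], [1.5e-16], [0])
        rng = np.random.default_rng(0)
        dt, t = 60.0, 0.0
        while len(pop) and t < 3600.0:
            grow_and_consume(pop, table, field, xi, dt, rng)
            divide_or_die(pop, table)
            t += dt
        assert t == pytest.approx(600.0 + dt, abs=dt)


class TestByproduct:
    def test_no_byproduct_without_beta(self):
        grid, state, field, table = setup_world()
        pop = Population([0], [1.5e-16], [0])
        m0 = field.total_mass().copy()
        grow_and_consume(pop, table, field, np.ones(grid.n_patches), 60.0,
                         np.random.default_rng(0))
        assert field.total_mass()[0] < m0[0]  # only consumption happened

    def test_exact_byproduct_mass(self):
        grid = uniform_patch_grid(n=8, phi=0.9)
        state = compute_hydration_state(grid, -500.0, MODEL)
        field = NutrientField(
            grid,
            state,
            [
                NutrientSpec("n1", c0=1e-3, boundary="closed"),
                NutrientSpec("n2", c0=0.0, boundary="closed"),
            ],
        )
        sp = SpeciesParams(
            "producer", mu_max=1 / 3600.0, k_s={"n1": 1e-3},
            y_max={"n1": 0.5}, alpha_m=0.0, beta=0.3, byproduct="n2",
        )
        table = SpeciesTable([sp], field.names)
        b, dt = 2e-16, 30.0
        pop = Population([0], [b], [7])
        mu = sp.mu_max * 0.5  # C = K_s
        grow_and_consume(pop, table, field, np.ones(grid.n_patches), dt,
                         np.random.default_rng(0))
        assert field.total_mass()[1] == pytest.approx(0.3 * mu * b * dt, rel=1e-6)
        # producer grew at (1 - beta) * mu_tilde
        assert pop.biomass[0] == pytest.approx(b * (1 + 0.7 * mu * dt), rel=1e-9)

    def test_producer_consumer_mass_ledger(self):
        """With unit yields and no maintenance, substrate + biomass + residual
        by-product is conserved in a closed producer/consumer system."""
        grid = uniform_patch_grid(n=8, phi=0.9)
        state = compute_hydration_state(grid, -500.0, MODEL)
        field = NutrientField(
            grid,
            state,
            [
                NutrientSpec("n1", c0=1e-3, boundary="closed"),
                NutrientSpec("n2", c0=0.0, boundary="closed"),
            ],
        )
        species = [
            SpeciesParams("producer", mu_max=1 / 3600.0, k_s={"n1": 1e-3},
                          y_max={"n1": 1.0}, alpha_m=0.0, beta=0.25,
                          byproduct="n2"),
            SpeciesParams("consumer", mu_max=1 / 3600.0, k_s={"n2": 5e-4},
                          y_max={"n2": 1.0}, alpha_m=0.0),
        ]
        table = SpeciesTable(species, field.names)
        pop = Population([0, 1], [2e-16, 2e-16], [7, 7])
        xi = np.ones(grid.n_patches)
        rng = np.random.default_rng(4)
        total0 = field.total_mass().sum() + pop.biomass.sum()
        for _ in range(200):
            grow_and_consume(pop, table, field, xi, 60.0, rng)
        total = field.total_mass().sum() + pop.biomass.sum()
        assert total == pytest.approx(total0, rel=1e-9)


# ----------------------------------------------------------------------
class TestSwimSpeed:
    def test_bulk_speed_limit(self):
        # v -> v0 = 14 um/s as the film becomes deep compared to the cell
        assert MODEL.speed(1.0) == pytest.approx(14e-6, rel=1e-3)
        assert MODEL.speed(1e-3) == pytest.approx(14e-6, rel=0.05)

    def test_sessile_below_threshold(self):
        w_th = MODEL.threshold_film()
        assert MODEL.speed(w_th * 0.99) == 0.0
        assert MODEL.speed(w_th * 1.01) > 0.0

    def test_monotone_in_film(self):
        w = np.logspace(-7, -3, 200)
        v = MODEL.speed(w)
        assert np.all(np.diff(v) >= -1e-18)

    def test_wet_limit_mean_speed_anchor(self):
        """Phi=0.4, D=1.8 reduces the wet-limit speed from 14 to ~10 um/s."""
        w = effective_film_thickness(RoughnessParams(Phi=0.4, D=1.8), -100.0)
        assert MODEL.speed(w) == pytest.approx(10e-6, rel=0.02)


class TestStepProbabilities:
    def test_normalised(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(1e-6, 1e-5, 7)
        mu = rng.uniform(0, 1e-4, 7)
        p = step_probabilities(w, mu, alpha=10.0, l_p=5e-4)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)

    def test_symmetric_case_uniform(self):
        p = step_probabilities(np.full(7, 2e-6), np.zeros(7), 5.0, 5e-4)
        assert np.allclose(p, 1.0 / 7.0)

    def test_strong_gradient_selects_direction(self):
        mu = np.zeros(7)
        mu[2] = 1.0  # enormous gradient along direction 2
        p = step_probabilities(np.full(7, 2e-6), mu, alpha=1.0, l_p=5e-4)
        assert p.argmax() == 2
        assert p[2] > 0.999

    def test_hand_computed_three_direction_case(self):
        w = np.array([1e-6, 2e-6, 0, 0, 0, 0, 1e-6])
        mu = np.array([1e-4, 0, 0, 0, 0, 0, 0])
        alpha, l_p = 100.0, 5e-4
        weights = w * np.exp(alpha * (mu - mu[6]) / l_p)
        weights[6] = w[6]
        expected = weights / weights.sum()
        p = step_probabilities(w, mu, alpha, l_p)
        assert np.allclose(p, expected)

    def test_invalid_directions_masked(self):
        w = np.full(7, 1e-6)
        valid = np.zeros(7, bool)
        p = step_probabilities(w, np.zeros(7), 1.0, 5e-4, valid=valid)
        assert p[6] == 1.0  # nowhere to go: stay


class TestMoveCells:
    def test_sessile_patch_pins_cells(self):
        grid, state, field, table = setup_world(psi=-1e4)  # dry: all sessile
        assert not state.motile.any()
        pop = Population([0], [1.5e-16], [10])
        moved = move_cells(pop, table, grid, state, field, 600.0,
                          np.random.default_rng(0))
        assert moved == 0
        assert pop.displacement[0] == 0.0

    def test_first_crossing_time(self):
        """At xi = P the first crossing happens after l_p/(v xi) seconds."""
        grid, state, field, table = setup_world(phi=0.9, psi=-500.0)
        assert state.motile.all()
        i = 27
        pop = Population([0], [1.5e-16], [i])
        dt = 5.0
        expected = grid.l_p / (state.xi[i] * state.swim_speed[i])
        rng = np.random.default_rng(0)
        t, moved = 0.0, 0
        while moved == 0 and t < 10 * expected:
            moved = move_cells(pop, table, grid, state, field, dt, rng)
            t += dt
        assert t == pytest.approx(expected, abs=dt + 1e-9)

    def test_cells_stay_inside_habitat(self):
        grid, state, field, table = setup_world(phi=0.9, psi=-500.0)
        pop = Population([0] * 200, [1.5e-16] * 200, [27] * 200)
        lab0 = state.labels[27]
        rng = np.random.default_rng(1)
        for _ in range(300):
            move_cells(pop, table, grid, state, field, 30.0, rng)
        assert np.all(state.labels[pop.patch] == lab0)

    def test_unbiased_walk_is_diffusive(self):
        """Mean squared displacement grows linearly in time (chi0 = 0)."""
        grid, state, field, table = setup_world(
            n=24, phi=0.9, psi=-500.0,
            species=[simple_species(chi0=0.0)],
        )
        n_walkers = 1000
        start = 12 * 24 + 12  # domain centre, far from the boundary
        pop = Population([0] * n_walkers, [1.5e-16] * n_walkers,
                         [start] * n_walkers)
        rng = np.random.default_rng(2)
        dt = 30.0
        pos0 = grid.lattice.positions[start]

        def msd():
            d = grid.lattice.positions[pop.patch] - pos0
            return (d**2).sum(axis=1).mean()

        crossing = grid.l_p / (state.xi[start] * state.swim_speed[start])
        n1 = int(round(12 * crossing / dt))  # ~12 crossings
        for _ in range(n1):
            move_cells(pop, table, grid, state, field, dt, rng)
        m1 = msd()
        for _ in range(n1):
            move_cells(pop, table, grid, state, field, dt, rng)
        m2 = msd()
        assert m2 / m1 == pytest.approx(2.0, rel=0.25)


class TestPopulationDoubling:
    def test_doubling_time_matches_net_growth_rate(self):
        """500 cells at saturating C and xi=1 double in ln2/mu_tilde +/- 5%."""
        sp = simple_species(alpha_m=0.1)
        grid, state, field, table = setup_world(species=[sp], c0=1.0)
        xi = np.ones(grid.n_patches)
        rng = np.random.default_rng(5)
        n0 = 500
        pop = Population(
            np.zeros(n0, int),
            np.full(n0, 1.5e-16),
            rng.integers(0, grid.n_patches, n0),
        )
        mu_tilde = sp.mu_max * (1.0 / (1 + 1e-3) - 0.1)
        t_double = np.log(2) / mu_tilde
        b0 = pop.biomass.sum()
        dt, t = 60.0, 0.0
        while pop.biomass.sum() < 2 * b0:
            grow_and_consume(pop, table, field, xi, dt, rng)
            divide_or_die(pop, table)
            t += dt
        assert t == pytest.approx(t_double, rel=0.05)
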