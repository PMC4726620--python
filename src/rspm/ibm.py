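"""Individual-based microbial dynamics.

Cells carry biomass, a patch location, an accumulated in-patch displacement
and a starvation clock.  Each step they grow by multi-nutrient Monod
kinetics with maintenance (mu_tilde = mu - alpha_m * mu_max), consume
substrate scaled by a stochastic nutrient-sharing factor
f_p = xi + chi_p (1 - xi), divide at a fixed mass threshold, die after
sustained starvation, optionally excrete a by-product nutrient, and move by
a hydration-limited chemotactic biased random walk: displacement accrues at
the patch swim speed, and once it exceeds the tortuous path length
l_p / xi the cell jumps to a neighbour drawn with probability
p_i ~ w_i * exp(alpha * grad(mu) . e_i), never leaving its aqueous habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytics import chemotactic_alpha
from .connectivity import HydrationState
from .grid import HexLattice
from .surface import PatchGrid
from .transport import NutrientField

__all__ = [
    "SpeciesParams",
    "SpeciesTable",
    "Population",
    "specific_growth_rate",
    "nutrient_sharing_factor",
    "grow_and_consume",
    "divide_or_die",
    "byproduct_production",
    "step_probabilities",
    "move_cells",
]

#: Calibrated chemotactic sensitivity (m^2/s); see rspm.calibration.
CAL_CHI0 = 5.556123e-10


@dataclass(frozen=True)
class SpeciesParams:
    """Physiology of one species.

    ``k_s``/``y_max`` map nutrient name -> half-saturation (kg/m^3) and
    biomass yield (kg biomass per kg substrate); a species consumes exactly
    the nutrients listed there.  ``byproduct`` names a nutrient excreted at
    rate beta * mu * b (the producer then grows at (1-beta) * mu_tilde).
    """

    name: str
    mu_max: float = 1.0 / 3600.0  # s^-1
    k_s: dict = field(default_factory=lambda: {"glucose": 1e-3})
    y_max: dict = field(default_factory=lambda: {"glucose": 0.5})
    alpha_m: float = 0.1  # maintenance fraction, m = alpha_m * mu_max
    chi0: float = CAL_CHI0  # m^2/s chemotactic sensitivity
    t0: float = 1.0  # s mean run time (cancels in the drift closure)
    initial_mass: float = 1.5e-16  # kg
    division_mass: float = 3.0e-16  # kg, 2x initial mass
    starvation_death_time: float = 24 * 3600.0  # s
    beta: float = 0.0  # by-product yield in [0, 1)
    byproduct: str | None = None

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if not self.k_s or set(self.k_s) != set(self.y_max):
            raise ValueError("k_s and y_max must cover the same nutrients")
        if any(v <= 0 for v in self.k_s.values()):
            raise ValueError("half-saturation constants must be positive")
        if any(v <= 0 for v in self.y_max.values()):
            raise ValueError("yields must be positive")
        if not 0 <= self.beta < 1:
            raise ValueError("by-product yield beta must lie in [0, 1)")
        if self.beta > 0 and self.byproduct is None:
            raise ValueError("beta > 0 requires a by-product nutrient")
        if self.division_mass <= self.initial_mass:
            raise ValueError("division_mass must exceed initial_mass")
        if not 0 <= self.alpha_m < 1:
            raise ValueError("maintenance fraction must lie in [0, 1)")


class SpeciesTable:
    """Species parameters compiled to arrays against a nutrient list."""

    def __init__(self, species: list[SpeciesParams], nutrient_names: list[str]):
        if not species:
            raise ValueError("need at least one species")
        self.species = list(species)
        self.nutrients = list(nutrient_names)
        n_s, n_k = len(species), len(nutrient_names)
        self.mu_max = np.array([s.mu_max for s in species])
        self.alpha_m = np.array([s.alpha_m for s in species])
        self.chi0 = np.array([s.chi0 for s in species])
        self.beta = np.array([s.beta for s in species])
        self.initial_mass = np.array([s.initial_mass for s in species])
        self.division_mass = np.array([s.division_mass for s in species])
        self.death_time = np.array([s.starvation_death_time for s in species])
        self.consumes = np.zeros((n_s, n_k), dtype=bool)
        self.k_s = np.full((n_s, n_k), np.nan)
        self.inv_y = np.zeros((n_s, n_k))
        self.byproduct_idx = np.full(n_s, -1, dtype=np.int64)
        for i, s in enumerate(species):
            for nut, ks in s.k_s.items():
                if nut not in nutrient_names:
                    raise ValueError(f"species {s.name!r}: unknown nutrient {nut!r}")
                j = nutrient_names.index(nut)
                self.consumes[i, j] = True
                self.k_s[i, j] = ks
                self.inv_y[i, j] = 1.0 / s.y_max[nut]
            if s.byproduct is not None:
                if s.byproduct not in nutrient_names:
                    raise ValueError(
                        f"species {s.name!r}: unknown by-product {s.byproduct!r}"
                    )
                self.byproduct_idx[i] = nutrient_names.index(s.byproduct)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def monod_fraction(self, C: np.ndarray) -> np.ndarray:
        """min-law Monod fraction per (species, patch): (n_s, n_patches)."""
        # frac[s, i] = min over consumed nutrients j of C[i,j]/(Ks[s,j]+C[i,j])
        C = np.asarray(C, dtype=float)
        frac = np.ones((self.n_species, C.shape[0]))
        for s in range(self.n_species):
            js = np.flatnonzero(self.consumes[s])
            m = C[:, js] / (self.k_s[s, js][None, :] + C[:, js])
            frac[s] = m.min(axis=1)
        return frac

    def growth_rate_field(self, C: np.ndarray) -> np.ndarray:
        """Specific growth rate field mu_s(patch) = mu_max_s * min-law frac."""
        return self.mu_max[:, None] * self.monod_fraction(C)


# ----------------------------------------------------------------------
# Cell container (struct of arrays)
# ----------------------------------------------------------------------

class Population:
    """Living cells as parallel arrays (species, biomass, patch, ...)."""

    def __init__(self, species, biomass, patch):
        self.species = np.asarray(species, dtype=np.int64).copy()
        self.biomass = np.asarray(biomass, dtype=float).copy()
        self.patch = np.asarray(patch, dtype=np.int64).copy()
        n = self.species.size
        self.displacement = np.zeros(n)
        self.starvation = np.zeros(n)

    def __len__(self) -> int:
        return self.species.size

    @classmethod
    def inoculate(
        cls, table: SpeciesTable, patches, counts_per_species, rng
    ) -> "Population":
        """Place ``counts_per_species[s]`` cells of each species uniformly at
        random over the given patches, at their initial mass."""
        patches = np.asarray(patches, dtype=np.int64)
        sp, pa = [], []
        for s, n in enumerate(np.atleast_1d(counts_per_species)):
            sp.append(np.full(int(n), s, dtype=np.int64))
            pa.append(rng.choice(patches, size=int(n), replace=True))
        species = np.concatenate(sp) if sp else np.zeros(0, np.int64)
        patch = np.concatenate(pa) if pa else np.zeros(0, np.int64)
        return cls(species, table.initial_mass[species], patch)

    def keep(self, mask: np.ndarray) -> None:
        self.species = self.species[mask]
        self.biomass = self.biomass[mask]
        self.patch = self.patch[mask]
        self.displacement = self.displacement[mask]
        self.starvation = self.starvation[mask]

    def abundances(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species)

    def positions(self, lattice: HexLattice) -> np.ndarray:
        return lattice.positions[self.patch]


# ----------------------------------------------------------------------
# Growth
# ----------------------------------------------------------------------

def specific_growth_rate(species: SpeciesParams, concentrations: dict):
    """(mu, mu_tilde) for one species at the given concentrations (kg/m^3).

    mu = mu_max * min_j C_j/(K_s,j + C_j); mu_tilde = mu - alpha_m * mu_max
    (may be negative: net biomass loss to maintenance).
    """
    fracs = [
        concentrations[nut] / (ks + concentrations[nut])
        if concentrations[nut] > 0
        else 0.0
        for nut, ks in species.k_s.items()
    ]
    mu = species.mu_max * min(fracs)
    return mu, mu - species.alpha_m * species.mu_max


def nutrient_sharing_factor(xi, rng, size=None):
    """f_p = xi + chi_p (1 - xi), chi_p ~ U[0, 1]; f_p = 1 when xi = 1."""
    xi = np.asarray(xi, dtype=float)
    chi_p = rng.uniform(0.0, 1.0, size=size if size is not None else xi.shape)
    out = xi + chi_p * (1.0 - xi)
    return out if np.ndim(out) else float(out)


def grow_and_consume(
    pop: Population,
    table: SpeciesTable,
    field: NutrientField,
    xi: np.ndarray,
    dt: float,
    rng,
) -> np.ndarray:
    """One growth/uptake step for every cell; returns realised uptake (kg).

    Each cell's realised Monod rate is its sharing factor f_p times the
    patch-level Monod rate, so consumed substrate and produced biomass close
    the yield ledger exactly.  If a patch runs out of a nutrient the uptake
    is capped and growth rescaled proportionally.  Producers divert a
    fraction beta of gross growth to their by-product nutrient.  Starvation
    clocks advance while net growth is non-positive and reset otherwise.
    """
    n = len(pop)
    n_k = len(field.names)
    if n == 0:
        return np.zeros((field.grid.n_patches, n_k))

    s, patch, b = pop.species, pop.patch, pop.biomass
    frac = table.monod_fraction(field.C)  # (n_s, n_patches)
    f_p = nutrient_sharing_factor(xi[patch], rng)
    mu = f_p * table.mu_max[s] * frac[s, patch]  # gross, sharing-limited

    # desired uptake per nutrient: (mu / Y) * b * dt for consumed nutrients
    per_cell = (mu * b * dt)[:, None] * table.inv_y[s]  # (n, n_k)
    want = np.zeros((field.grid.n_patches, n_k))
    np.add.at(want, patch, per_cell)
    realised = field.apply_consumption(want)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale_pn = np.where(want > 0, realised / np.maximum(want, 1e-300), 1.0)
    # a cell is limited by the scarcest of its consumed nutrients in its patch
    cell_scale = np.where(table.consumes[s], scale_pn[patch], 1.0).min(axis=1)
    mu_real = mu * cell_scale

    mu_tilde = mu_real - table.alpha_m[s] * table.mu_max[s]
    growth_factor = np.where(table.beta[s] > 0, 1.0 - table.beta[s], 1.0)
    pop.biomass = b * np.maximum(1.0 + growth_factor * mu_tilde * dt, 0.0)

    byproduct_production(pop, table, field, mu_real, b, dt)

    starving = mu_tilde <= 0
    pop.starvation = np.where(starving, pop.starvation + dt, 0.0)
    return realised


def byproduct_production(
    pop: Population,
    table: SpeciesTable,
    field: NutrientField,
    mu_real: np.ndarray,
    biomass: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Excrete dN = beta * mu * b * dt into each producer's by-product pool."""
    s = pop.species
    producers = (table.beta[s] > 0) & (table.byproduct_idx[s] >= 0)
    n_k = len(field.names)
    mass = np.zeros((field.grid.n_patches, n_k))
    if np.any(producers):
        dm = table.beta[s[producers]] * mu_real[producers] * biomass[producers] * dt
        np.add.at(
            mass,
            (pop.patch[producers], table.byproduct_idx[s[producers]]),
            dm,
        )
        field.add_mass(mass)
    return mass


def divide_or_die(pop: Population, table: SpeciesTable) -> None:
    """Divide cells above the mass threshold; remove starved-out cells.

    Division yields two daughters of half mass in the same patch with reset
    displacement (total biomass conserved); death removes cells whose
    starvation clock exceeds the species threshold.
    """
    alive = pop.starvation <= table.death_time[pop.species]
    alive &= pop.biomass > 0
    pop.keep(alive)

    dividing = pop.biomass >= table.division_mass[pop.species]
    if not np.any(dividing):
        return
    pop.biomass[dividing] *= 0.5
    pop.displacement[dividing] = 0.0
    pop.species = np.concatenate([pop.species, pop.species[dividing]])
    pop.biomass = np.concatenate([pop.biomass, pop.biomass[dividing]])
    pop.patch = np.concatenate([pop.patch, pop.patch[dividing]])
    pop.displacement = np.concatenate(
        [pop.displacement, np.zeros(int(dividing.sum()))]
    )
    pop.starvation = np.concatenate(
        [pop.starvation, pop.starvation[dividing]]
    )


# ----------------------------------------------------------------------
# Motion
# ----------------------------------------------------------------------

def step_probabilities(films, mu_values, alpha, l_p, valid=None) -> np.ndarray:
    """Crossing probabilities over the 7 directions (6 neighbours + stay).

    p_i ~ w_i * exp(alpha * (mu_i - mu_self)/l_p); index 6 is the current
    patch with zero gradient projection.  ``valid`` masks admissible
    neighbour moves (out-of-domain or out-of-habitat directions).
    """
    w = np.asarray(films, dtype=float)
    mu = np.asarray(mu_values, dtype=float)
    if w.shape[-1] != 7 or mu.shape[-1] != 7:
        raise ValueError("expected 7 directions (6 neighbours + self)")
    proj = (mu - mu[..., 6:7]) / l_p
    proj[..., 6] = 0.0
    weights = w * np.exp(np.clip(alpha * proj, -50.0, 50.0))
    if valid is not None:
        v = np.asarray(valid, bool).copy()
        v[..., 6] = True  # staying put is always admissible
        weights = np.where(v, weights, 0.0)
    total = weights.sum(axis=-1, keepdims=True)
    stay_only = np.zeros_like(weights)
    stay_only[..., 6] = 1.0
    return np.where(total > 0, weights / np.maximum(total, 1e-300), stay_only)


def move_cells(
    pop: Population,
    table: SpeciesTable,
    grid: PatchGrid,
    state: HydrationState,
    field: NutrientField,
    dt: float,
    rng,
) -> int:
    """Advance displacements and relocate cells that cross patches.

    Sessile patches pin their cells.  On motile patches displacement grows
    by v dt; when it exceeds the tortuous path length l_p / xi the cell
    draws one of the 7 directions from the film-weighted chemotactic
    probabilities and crossings are confined to the cell's aqueous habitat.
    Returns the number of crossings.
    """
    if len(pop) == 0:
        return 0
    patch = pop.patch
    motile = state.motile[patch]
    v = state.swim_speed[patch]
    pop.displacement[motile] += v[motile] * dt

    with np.errstate(divide="ignore"):
        threshold = np.where(
            state.xi[patch] > 0, grid.l_p / state.xi[patch], np.inf
        )
    crossing = motile & (pop.displacement >= threshold)
    idx = np.flatnonzero(crossing)
    if idx.size == 0:
        return 0

    lattice = grid.lattice
    nbr = lattice.neighbors[patch[idx]]  # (m, 6)
    safe = np.clip(nbr, 0, None)
    films7 = np.column_stack([state.w_eff[safe], state.w_eff[patch[idx]]])
    valid = np.column_stack(
        [
            (nbr >= 0)
            & state.motile[safe]
            & (state.labels[safe] == state.labels[patch[idx]][:, None]),
            np.ones(idx.size, bool),
        ]
    )

    # growth-rate field per species present among the movers
    mu_field = table.growth_rate_field(field.C)  # (n_s, n_patches)
    s = pop.species[idx]
    mu7 = np.column_stack(
        [mu_field[s[:, None], safe], mu_field[s, patch[idx]]]
    )
    alpha = chemotactic_alpha(
        table.chi0[s], table.mu_max[s], state.swim_speed[patch[idx]]
    )[:, None]
    probs = step_probabilities(films7, mu7, alpha, grid.l_p, valid=valid)

    choice = (probs.cumsum(axis=1) > rng.uniform(size=(idx.size, 1))).argmax(axis=1)
    dest = np.where(choice == 6, patch[idx], safe[np.arange(idx.size), np.minimum(choice, 5)])
    pop.patch[idx] = dest
    pop.displacement[idx] = 0.0
    return int(idx.size)
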