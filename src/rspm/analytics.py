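"""Population-level chemotaxis theory and community metrics.

The biased-random-walk locomotion model has a closed-form population drift:
with run times T(u) = t0 * exp(alpha |grad mu| u) in direction cosine u, the
net drift fraction of the swim speed is the Bessel ratio

    R_c(x) = I_1(x) / I_0(x),    x = alpha |grad mu|,

the chemotactic retardation factor.  It yields effective velocities,
chemotactic residence times, and an analytic colony expansion rate used as
an independent check on the individual-based simulator.  Community metrics
cover the normalised Shannon evenness, the coexistence index, and colony
diameter/expansion estimators.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

from .connectivity import mean_field_local_connectivity
from .motility import DEFAULT_FORCE_MODEL, ForceModel
from .surface import PhysicsConstants, RoughnessParams, effective_film_thickness

__all__ = [
    "retardation_factor",
    "chemotactic_alpha",
    "effective_velocity",
    "expected_residence_time",
    "analytic_expansion_rate",
    "shannon_normalized",
    "coexistence_index",
    "coexistence_indices",
    "colony_diameter",
    "expansion_rate_fit",
]


def retardation_factor(x):
    """Chemotactic retardation R_c(x) = I1(x)/I0(x), monotone on [0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("bias strength x = alpha*|grad mu| must be >= 0")
    # exponentially scaled Bessels avoid overflow for strong bias
    out = i1e(x) / i0e(x)
    return out if out.ndim else float(out)


def chemotactic_alpha(chi0: float, mu_max: float, v):
    """alpha = chi_0 / (2 mu_max v), s; balances sensitivity and speed."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("alpha is defined for swimming cells only (v > 0)")
    out = chi0 / (2.0 * mu_max * v)
    return out if out.ndim else float(out)


def effective_velocity(v: float, alpha: float, grad_mu) -> np.ndarray:
    """Population drift vector v_eff = v * R_c(alpha |grad mu|) * grad/|grad|."""
    g = np.asarray(grad_mu, dtype=float)
    norm = np.linalg.norm(g)
    if norm == 0:
        return np.zeros_like(g)
    return v * retardation_factor(alpha * norm) * g / norm


def expected_residence_time(t_bar_r: float, r_c: float) -> float:
    """T* = T_bar_r / R_c; +inf when the walk is unbiased (R_c = 0)."""
    if r_c <= 0:
        return np.inf
    return t_bar_r / r_c


def analytic_expansion_rate(
    params: RoughnessParams,
    psi_m: float,
    chi0: float,
    mu_max: float,
    growth_fraction: float,
    l_p: float = 5e-4,
    model: ForceModel = DEFAULT_FORCE_MODEL,
    phys: PhysicsConstants = PhysicsConstants(),
) -> float:
    """Steady-state chemotactic ring expansion rate (m/s), mean-field.

    The domain is summarised by its mean porosity: speed v(w_eff(Phi_bar)),
    connectivity xi from the mean-field percolation argument, and a
    one-patch-wide growth-rate front |grad mu| = mu_max*growth_fraction/l_p.
    The front advances at v_eff * xi = v * R_c(alpha |grad mu|) * xi; it is
    zero once capillary pinning stops swimming.
    """
    w = effective_film_thickness(params, psi_m, phys)
    v = model.speed(w)
    if v <= 0:
        return 0.0
    xi = mean_field_local_connectivity(params, psi_m, model, phys)
    grad_mu = mu_max * growth_fraction / l_p
    alpha = chemotactic_alpha(chi0, mu_max, v)
    return float(v * retardation_factor(alpha * grad_mu) * xi)


def analytic_expansion_radius(
    params: RoughnessParams,
    psi_m: float,
    t: float,
    chi0: float,
    mu_max: float,
    growth_fraction: float,
    **kw,
) -> float:
    """Ring radius R(t) for static hydration: rate * t."""
    return analytic_expansion_rate(
        params, psi_m, chi0, mu_max, growth_fraction, **kw
    ) * float(t)


# ----------------------------------------------------------------------
# Community metrics
# ----------------------------------------------------------------------

def shannon_normalized(abundances) -> float:
    """Normalised Shannon evenness H_D = -(1/ln Ns) sum p_i ln p_i in [0, 1].

    ``abundances`` holds one entry per species (zeros allowed, 0 ln 0 := 0);
    at least two species and a positive total are required.
    """
    n = np.asarray(abundances, dtype=float)
    if n.ndim != 1 or n.size < 2:
        raise ValueError("need abundances for at least two species")
    if np.any(n < 0):
        raise ValueError("abundances must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("total abundance must be positive")
    p = n / total
    nz = p > 0
    h = -(p[nz] * np.log(p[nz])).sum() / np.log(n.size)
    return float(h)


def coexistence_index(
    v_eff: float,
    net_growth_rate: float,
    cluster_patches: int,
    l_p: float = 5e-4,
) -> float:
    """CI = generation length / habitat linear size.

    Generation length is the distance travelled during one doubling,
    |v_eff| * ln2 / mu_net; habitat linear size is sqrt(patch count) * l_p.
    CI = 0 for sessile cells (v_eff = 0); CI = inf when the population is
    not growing (mu_net <= 0) but drifting.
    """
    if cluster_patches < 1:
        raise ValueError("cluster must contain at least one patch")
    if v_eff == 0:
        return 0.0
    if net_growth_rate <= 0:
        return np.inf
    t_gen = np.log(2.0) / net_growth_rate
    return float(abs(v_eff) * t_gen / (np.sqrt(cluster_patches) * l_p))


def coexistence_indices(population, table, state, field, grid) -> np.ndarray:
    """Per-species CI averaged over living cells at the current snapshot.

    Each cell contributes |v_eff| t_gen / L_cluster with the patch-local
    drift (speed times R_c of the strongest neighbour growth-rate
    difference), t_gen = ln2 / mu_tilde at the patch concentration, and the
    linear size of the cell's aqueous habitat.  Sessile cells contribute 0;
    cells with non-positive net growth are excluded from the average.
    """
    n_s = table.n_species
    out = np.zeros(n_s)
    if len(population) == 0:
        return out
    mu_field = table.growth_rate_field(field.C)  # (n_s, n_patches)
    sizes = state.habitat_sizes()
    nbr = grid.lattice.neighbors
    for s in range(n_s):
        cells = np.flatnonzero(population.species == s)
        if cells.size == 0:
            continue
        vals = []
        for patch in population.patch[cells]:
            v = state.swim_speed[patch]
            if not state.motile[patch] or v <= 0:
                vals.append(0.0)
                continue
            mu_t = mu_field[s, patch] - table.alpha_m[s] * table.mu_max[s]
            if mu_t <= 0:
                continue
            js = nbr[patch][nbr[patch] >= 0]
            grad = np.abs(mu_field[s, js] - mu_field[s, patch]).max() / grid.l_p
            alpha = chemotactic_alpha(table.chi0[s], table.mu_max[s], v)
            v_eff = v * retardation_factor(alpha * grad)
            cluster = sizes[state.labels[patch]]
            vals.append(
                coexistence_index(v_eff, mu_t, int(cluster), grid.l_p)
            )
        if vals:
            out[s] = float(np.mean(vals))
    return out


def colony_diameter(positions, origin, percentile: float = 95.0) -> float:
    """Colony diameter = 2 x the given percentile of radial cell distances."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[0] == 0:
        return 0.0
    r = np.linalg.norm(pos - np.asarray(origin, dtype=float), axis=1)
    return float(2.0 * np.percentile(r, percentile))


def expansion_rate_fit(
    times, diameters, domain_extent: float | None = None, window: float = 0.5
):
    """Radial expansion rate (m/s) from a colony-diameter time series.

    A straight line is fitted to diameter vs time over the final ``window``
    fraction of the pre-boundary transit (the series is truncated where the
    diameter first exceeds 80% of ``domain_extent``, if given); the radial
    rate is half the fitted diameter slope.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(diameters, dtype=float)
    if t.size != d.size or t.size < 2:
        raise ValueError("need matching time/diameter series of length >= 2")
    if domain_extent is not None:
        inside = d <= 0.8 * domain_extent
        stop = int(np.argmin(inside)) if not inside.all() else t.size
        stop = max(stop, 2)
        t, d = t[:stop], d[:stop]
    t0 = t[0] + (1.0 - window) * (t[-1] - t[0])
    sel = t >= t0
    if sel.sum() < 2:
        sel = np.ones_like(t, bool)
    slope = np.polyfit(t[sel], d[sel], 1)[0]
    return float(slope / 2.0)
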