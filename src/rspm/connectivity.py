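"""Hydration state: motile/sessile classification and habitat fragmentation.

At a given matric potential each patch gets an effective film thickness, a
swim speed, and an occupation probability p of swimmable pore regions.  A
patch is *motile* when (1) the film supports flagellated motion (v > 0) and
(2) p exceeds the patch's local percolation threshold, so the within-patch
residence time is finite.  Aqueous habitats are connected components of
motile patches under 6-neighbour hex adjacency; the global percolation
probability P is the largest-cluster fraction of the whole domain.  The
local connectivity is

    xi = P            if p > p_c
    xi = p * P        otherwise,

its inverse is the patch tortuosity, and the minimum residence time of a
cell in a patch is T_r = l_p / (v * xi) (infinite on sessile patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .motility import DEFAULT_FORCE_MODEL, ForceModel
from .surface import (
    PatchGrid,
    PhysicsConstants,
    RoughnessParams,
    adsorbed_film_thickness,
    effective_film_thickness,
    mean_pore_film,
    wetted_pore_area_fraction,
)

__all__ = [
    "HydrationState",
    "occupation_probability",
    "classify_motile",
    "label_aqueous_habitats",
    "local_connectivity",
    "compute_hydration_state",
    "mean_min_residence_time",
    "mean_field_local_connectivity",
]


def occupation_probability(
    params: RoughnessParams,
    psi_m: float,
    model: ForceModel = DEFAULT_FORCE_MODEL,
    phys: PhysicsConstants = PhysicsConstants(),
) -> float:
    """Expected occupation probability p of accessible surface-pore regions.

    Surface pores are the conduits of within-patch motion.  A pore region is
    accessible when capillary water stands on it and the water pocket is
    deep enough to swim in (pocket depth >= the force-model film threshold,
    so no second free parameter is introduced):

        F(psi) = area share of wetted, swimmable pore regions
        p      = F + (1 - F) * 1{v(h_mu(psi)) > 0}

    The second term covers the smooth-film route: when even the adsorbed
    film supports swimming, the whole patch is passable and p -> 1.  p is
    monotone non-increasing in |psi_m|, tends to 1 as psi_m -> 0- and to 0
    when films everywhere fall below the motility threshold.
    """
    w_th = model.threshold_film()
    f = wetted_pore_area_fraction(params, psi_m, phys, min_pocket=w_th)
    h = adsorbed_film_thickness(psi_m, phys)
    smooth = 1.0 if model.speed(h) > 0 else 0.0
    return float(f + (1.0 - f) * smooth)


def classify_motile(
    params: RoughnessParams,
    psi_m: float,
    p_c: float,
    model: ForceModel = DEFAULT_FORCE_MODEL,
    phys: PhysicsConstants = PhysicsConstants(),
) -> bool:
    """Motile iff v(w_eff) > 0 and p > p_c (single-patch convenience form)."""
    w = effective_film_thickness(params, psi_m, phys)
    if model.speed(w) <= 0:
        return False
    return occupation_probability(params, psi_m, model, phys) > p_c


def label_aqueous_habitats(motile_mask: np.ndarray, neighbors: np.ndarray):
    """Connected components of motile patches under hex adjacency.

    Returns ``(labels, P_global)``: labels are -1 on sessile patches and
    0..k-1 on motile ones; P_global is the largest-cluster fraction of the
    *total* patch count (0 for an empty mask).
    """
    motile = np.asarray(motile_mask, bool).ravel()
    n = motile.size
    labels = np.full(n, -1, dtype=np.int64)
    idx = np.flatnonzero(motile)
    if idx.size == 0:
        return labels, 0.0
    i = np.repeat(np.arange(n), neighbors.shape[1])
    j = neighbors.ravel()
    ok = (j >= 0) & motile[i] & motile[np.clip(j, 0, n - 1)]
    i, j = i[ok], j[ok]
    sub = np.full(n, -1, dtype=np.int64)
    sub[idx] = np.arange(idx.size)
    adj = coo_matrix(
        (np.ones(i.size), (sub[i], sub[j])), shape=(idx.size, idx.size)
    )
    n_comp, comp = connected_components(adj, directed=False)
    labels[idx] = comp
    largest = np.bincount(comp, minlength=n_comp).max()
    return labels, float(largest / n)


def local_connectivity(p, p_c, P_global):
    """Piecewise local connectivity xi = P if p > p_c else p * P."""
    p = np.asarray(p, dtype=float)
    xi = np.where(p > p_c, P_global, p * P_global)
    return xi if xi.ndim else float(xi)


@dataclass
class HydrationState:
    """Abiotic state of a domain at one matric potential (flat arrays)."""

    psi_m: float
    w_eff: np.ndarray  # m
    saturation: np.ndarray
    swim_speed: np.ndarray  # m/s
    occupation_p: np.ndarray
    motile: np.ndarray  # bool
    labels: np.ndarray  # habitat id, -1 if sessile
    P_global: float
    xi: np.ndarray
    residence_time: np.ndarray  # s, inf on sessile patches

    @property
    def tortuosity(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.xi > 0, 1.0 / self.xi, np.inf)

    @property
    def motile_fraction(self) -> float:
        return float(self.motile.mean())

    def habitat_sizes(self) -> np.ndarray:
        if self.labels.max() < 0:
            return np.zeros(0, dtype=np.int64)
        return np.bincount(self.labels[self.labels >= 0])


def compute_hydration_state(
    grid: PatchGrid,
    psi_m: float,
    model: ForceModel = DEFAULT_FORCE_MODEL,
) -> HydrationState:
    """Evaluate the full hydration state of a domain at psi_m.

    Exploits the affinity of w_eff in Phi: the pore-average film and wetted
    fraction are computed once per psi_m, then broadcast over the porosity
    field.
    """
    phys = grid.phys
    base = grid.roughness
    phi = grid.phi_flat
    pc = grid.pc_flat

    h = adsorbed_film_thickness(psi_m, phys)
    w_pore = mean_pore_film(base, psi_m, phys)
    w_eff = phi * w_pore + (1.0 - phi) * h

    sat_pore = mean_pore_film(base, -1.0, phys)
    h_sat = adsorbed_film_thickness(-1.0, phys)
    w_sat = phi * sat_pore + (1.0 - phi) * h_sat
    saturation = np.clip(w_eff / w_sat, 0.0, 1.0)

    v = model.speed(w_eff)

    p_scalar = occupation_probability(base, psi_m, model, phys)
    p = np.full(phi.shape, p_scalar)

    motile = (v > 0) & (p > pc)
    labels, P = label_aqueous_habitats(motile, grid.lattice.neighbors)
    xi = local_connectivity(p, pc, P)
    # xi only supports transport of cells on motile patches
    with np.errstate(divide="ignore"):
        t_r = np.where((v > 0) & (xi > 0), grid.l_p / (v * xi), np.inf)
    t_r = np.where(motile, t_r, np.inf)

    return HydrationState(
        psi_m=float(psi_m),
        w_eff=w_eff,
        saturation=saturation,
        swim_speed=v,
        occupation_p=p,
        motile=motile,
        labels=labels,
        P_global=P,
        xi=xi,
        residence_time=t_r,
    )


def mean_min_residence_time(state: HydrationState, over: str = "domain"):
    """Averaged minimum residence time T_bar_r = <l_p / (v xi)>.

    ``over='domain'`` averages over every patch and returns ``inf`` if any
    patch is sessile (the paper's domain average diverges at the onset of
    pinning); ``over='motile'`` averages over motile patches only.
    """
    if over == "domain":
        vals = state.residence_time
    elif over == "motile":
        vals = state.residence_time[state.motile]
        if vals.size == 0:
            return np.inf
    else:
        raise ValueError("over must be 'domain' or 'motile'")
    return float(np.mean(vals))


def mean_field_local_connectivity(
    params: RoughnessParams,
    psi_m: float,
    model: ForceModel = DEFAULT_FORCE_MODEL,
    phys: PhysicsConstants = PhysicsConstants(),
) -> float:
    """Domain-mean xi for the analytic theory: a uniform domain at the mean
    porosity either percolates (p > <p_c>(H): xi = 1) or fragments
    (xi = p)."""
    from .surface import percolation_threshold_stats

    p = occupation_probability(params, psi_m, model, phys)
    pc_mean, _ = percolation_threshold_stats(params.hurst)
    return 1.0 if p > pc_mean else float(p)
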