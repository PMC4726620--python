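"""Nutrient reaction–diffusion on the hex patch lattice.

Dissolved nutrients diffuse through the water films connecting adjacent
patches.  The exchange between two patches uses the thinner of the two films
as the joint cross-section, reduced by a Millington–Quirk saturation factor:

    g_ij = D_aq * tau_MQ(S_min) * (w_min * L_edge) / l_p        [m^3/s]

Concentrations evolve with an explicit, mass-conservative Euler step
dM_i = sum_j g_ij (C_j - C_i) dt followed by per-patch consumption, capped so
concentrations never go negative.  Boundary conditions are either closed
(zero-flux, total mass conserved) or Dirichlet (boundary patches pinned to
C0 after every step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .connectivity import HydrationState
from .surface import PatchGrid

__all__ = [
    "NutrientSpec",
    "NutrientField",
    "pairwise_conductance",
    "millington_quirk",
    "stable_dt",
]

MQ_EXPONENT = 7.0 / 3.0


def millington_quirk(saturation, exponent: float = MQ_EXPONENT):
    """Unsaturated tortuosity factor tau = S^(7/3) (switchable to 1.0)."""
    s = np.asarray(saturation, dtype=float)
    out = np.power(np.clip(s, 0.0, 1.0), exponent)
    return out if out.ndim else float(out)


def pairwise_conductance(
    w_i: float,
    w_j: float,
    s_i: float,
    s_j: float,
    d_aq: float,
    edge_length: float,
    centre_distance: float,
    mq_exponent: float = MQ_EXPONENT,
) -> float:
    """Conductance (m^3/s) between two adjacent patches.

    The thinner film sets both the cross-section and the saturation used in
    the Millington–Quirk factor; zero if either film vanishes.
    """
    w_min = min(w_i, w_j)
    if w_min <= 0:
        return 0.0
    s_min = s_i if w_i <= w_j else s_j
    tau = millington_quirk(s_min, mq_exponent)
    return float(d_aq * tau * w_min * edge_length / centre_distance)


@dataclass(frozen=True)
class NutrientSpec:
    """Configuration of one dissolved nutrient."""

    name: str
    d_aq: float = 1e-10  # m^2/s aqueous diffusivity
    c0: float = 1e-3  # kg/m^3 initial concentration (1 mg/L)
    boundary: str = "dirichlet"  # or "closed"

    def __post_init__(self) -> None:
        if self.d_aq <= 0:
            raise ValueError("aqueous diffusivity must be positive")
        if self.c0 < 0:
            raise ValueError("initial concentration must be non-negative")
        if self.boundary not in ("dirichlet", "closed"):
            raise ValueError("boundary must be 'dirichlet' or 'closed'")


class NutrientField:
    """Concentrations of one or more nutrients over a hydrated domain."""

    def __init__(
        self,
        grid: PatchGrid,
        state: HydrationState,
        nutrients: list[NutrientSpec],
        mq_exponent: float = MQ_EXPONENT,
    ):
        if not nutrients:
            raise ValueError("need at least one nutrient")
        self.grid = grid
        self.nutrients = list(nutrients)
        self.names = [n.name for n in nutrients]
        if len(set(self.names)) != len(self.names):
            raise ValueError("nutrient names must be unique")
        self.mq_exponent = mq_exponent
        self.boundary_mask = grid.lattice.boundary_mask()
        n = grid.n_patches
        self.C = np.tile(
            np.array([sp.c0 for sp in nutrients]), (n, 1)
        )  # (n_patches, n_nutrients)
        self.update_hydration(state)

    # ------------------------------------------------------------------
    def update_hydration(self, state: HydrationState) -> None:
        """Recompute water volumes and the conductance operator for a new
        hydration state (film geometry enters every edge)."""
        self.state = state
        area = self.grid.lattice.patch_area
        self.V_w = area * state.w_eff  # m^3 per patch
        edges = self.grid.lattice.edges()
        i, j = edges[:, 0], edges[:, 1]
        w_min = np.minimum(state.w_eff[i], state.w_eff[j])
        s_min = np.where(
            state.w_eff[i] <= state.w_eff[j],
            state.saturation[i],
            state.saturation[j],
        )
        tau = millington_quirk(s_min, self.mq_exponent)
        geom = tau * w_min * self.grid.lattice.edge_length / self.grid.l_p
        n = self.grid.n_patches
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([geom, geom, -geom, -geom])
        #: geometric graph Laplacian; per-nutrient conductance = d_aq * L
        self.laplacian: csr_matrix = coo_matrix(
            (vals, (rows, cols)), shape=(n, n)
        ).tocsr()
        self._geom_degree = np.asarray(
            coo_matrix((np.concatenate([geom, geom]), (np.concatenate([i, j]),
                        np.zeros(2 * geom.size, dtype=np.int64))), shape=(n, 1)
                       ).todense()
        ).ravel()

    # ------------------------------------------------------------------
    def stable_dt(self, safety: float = 0.5):
        """Largest stable explicit step: safety * min_i V_w,i / sum_j g_ij."""
        d_max = max(sp.d_aq for sp in self.nutrients)
        deg = d_max * self._geom_degree
        with np.errstate(divide="ignore"):
            bound = np.where(deg > 0, self.V_w / np.maximum(deg, 1e-300), np.inf)
        dt = safety * bound.min()
        return float(dt)

    def diffusion_step(self, dt: float) -> None:
        """One conservative explicit diffusion step of length dt (s)."""
        limit = self.stable_dt(safety=1.0)
        if dt > limit * (1 + 1e-12):
            raise ValueError(
                f"dt={dt:g}s violates the diffusion stability bound {limit:g}s"
            )
        flux = self.laplacian @ self.C  # (n, k) geometric part
        d_aq = np.array([sp.d_aq for sp in self.nutrients])
        self.C += (dt * d_aq) * flux / self.V_w[:, None]
        np.clip(self.C, 0.0, None, out=self.C)
        self.apply_boundary()

    def apply_boundary(self) -> None:
        for k, sp in enumerate(self.nutrients):
            if sp.boundary == "dirichlet":
                self.C[self.boundary_mask, k] = sp.c0

    # ------------------------------------------------------------------
    def apply_consumption(self, uptake_mass: np.ndarray) -> np.ndarray:
        """Remove nutrient mass (kg, shape (n_patches, n_nutrients)).

        Uptake is capped by the mass available in each patch; the realised
        uptake is returned so growth can be rescaled consistently.
        """
        uptake = np.asarray(uptake_mass, dtype=float)
        avail = self.C * self.V_w[:, None]
        realised = np.minimum(uptake, avail)
        self.C = (avail - realised) / self.V_w[:, None]
        np.clip(self.C, 0.0, None, out=self.C)
        return realised

    def add_mass(self, mass: np.ndarray) -> None:
        """Add nutrient mass (kg) per patch (e.g. metabolic by-products)."""
        self.C += np.asarray(mass, dtype=float) / self.V_w[:, None]

    # ------------------------------------------------------------------
    def total_mass(self) -> np.ndarray:
        """Total dissolved mass per nutrient (kg)."""
        return (self.C * self.V_w[:, None]).sum(axis=0)

    def index(self, name: str) -> int:
        return self.names.index(name)


def stable_dt(field: NutrientField, safety: float = 0.5) -> float:
    """Module-level convenience wrapper."""
    return field.stable_dt(safety=safety)
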