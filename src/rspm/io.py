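"""Tabular and HDF5 export of domains, hydration states and cells."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import HydrationState
from .surface import PatchGrid


def hydration_to_frame(grid: PatchGrid, state: HydrationState) -> pd.DataFrame:
    """Per-patch table: row, col, Phi, p_c, w_eff, S, v, p, motile, habitat."""
    rows, cols = grid.lattice.rowcol(np.arange(grid.n_patches))
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "Phi": grid.phi_flat,
            "p_c": grid.pc_flat,
            "w_eff_m": state.w_eff,
            "saturation": state.saturation,
            "swim_speed_m_s": state.swim_speed,
            "occupation_p": state.occupation_p,
            "motile": state.motile,
            "habitat": state.labels,
            "xi": state.xi,
            "residence_time_s": state.residence_time,
        }
    )


def hydration_to_csv(grid: PatchGrid, state: HydrationState, path) -> None:
    hydration_to_frame(grid, state).to_csv(path, index=False)


def cells_to_frame(population, table) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [table.species[s].name for s in population.species],
            "patch": population.patch,
            "biomass_kg": population.biomass,
            "displacement_m": population.displacement,
            "starvation_s": population.starvation,
        }
    )


def cells_to_csv(population, table, path) -> None:
    cells_to_frame(population, table).to_csv(path, index=False)


def domain_to_hdf5(grid: PatchGrid, state: HydrationState, field, path) -> None:
    """Full fields (porosity, hydration, nutrient concentrations) as HDF5."""
    import h5py

    shape = (grid.lattice.n_rows, grid.lattice.n_cols)
    with h5py.File(Path(path), "w") as f:
        dom = f.create_group("domain")
        dom.create_dataset("Phi", data=grid.Phi_field)
        dom.create_dataset("p_c", data=grid.pc_field)
        dom.attrs.update(
            {
                "D": grid.roughness.D,
                "H": grid.H,
                "r_min": grid.roughness.r_min,
                "r_max": grid.roughness.r_max,
                "l_p": grid.l_p,
            }
        )
        hyd = f.create_group("hydration")
        hyd.attrs["psi_m_Pa"] = state.psi_m
        for name in (
            "w_eff",
            "saturation",
            "swim_speed",
            "occupation_p",
            "xi",
        ):
            hyd.create_dataset(name, data=getattr(state, name).reshape(shape))
        hyd.create_dataset("motile", data=state.motile.reshape(shape))
        hyd.create_dataset("habitat", data=state.labels.reshape(shape))
        if field is not None:
            nut = f.create_group("nutrients")
            for k, name in enumerate(field.names):
                nut.create_dataset(name, data=field.C[:, k].reshape(shape))
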