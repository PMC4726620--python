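"""Flagellated swimming speed in thin water films.

Cell speed follows a force balance v = v0 (F_M - F_lambda - F_c)/F_M between
flagellar propulsion F_M, cell–surface lubrication drag F_lambda (diverging
as the film thins towards the cell radius) and capillary pinning F_c
(proportional to surface tension times the exposed cell perimeter once the
film is thinner than the cell diameter).  Speeds are clamped at zero: when
capillarity dominates, the cell is sessile.

The two dimensionless drag constants are calibrated once against the two
printed anchors of the reference surfaces (mean speed ~10 um/s at the wet
limit for Phi=0.4, D=1.8 with v0=14 um/s; speed vanishing at psi_m = -2 kPa
for Phi=0.5, D=1.8).  ``scripts/calibrate_forces.py`` regenerates them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["ForceModel", "swim_speed", "DEFAULT_FORCE_MODEL"]

#: Calibrated drag constants (regenerate with scripts/calibrate_forces.py).
CAL_DRAG_COEFF = 5.4848360
CAL_DRAG_EXPONENT = 0.7476053


@dataclass(frozen=True)
class ForceModel:
    """Force balance for flagellated motion in a film of thickness w.

    Dimensionless force ratios relative to the propulsion force F_M:

    - drag:    F_lambda/F_M = drag_coeff * (a / (w - a))^drag_exponent for
               w > a (cell radius a), infinite below;
    - pinning: F_c/F_M = pinning_strength * sigma * pi * d * (1 - w/d) / F_M
               for w < d (cell diameter), zero above.
    """

    v0: float = 14e-6  # m/s, bulk-water swimming speed
    cell_radius: float = 0.5e-6  # m
    propulsion_force: float = 0.57e-12  # N, flagellar thrust scale
    drag_coeff: float = CAL_DRAG_COEFF
    drag_exponent: float = CAL_DRAG_EXPONENT
    pinning_strength: float = 1.0  # fraction of the contact line engaged
    surface_tension: float = 0.072  # N/m

    @property
    def cell_diameter(self) -> float:
        return 2.0 * self.cell_radius

    # ------------------------------------------------------------------
    def drag_ratio(self, w):
        """F_lambda / F_M."""
        w = np.asarray(w, dtype=float)
        gap = w - self.cell_radius
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(
                gap > 0,
                self.drag_coeff
                * (self.cell_radius / np.maximum(gap, 1e-300)) ** self.drag_exponent,
                np.inf,
            )
        return ratio if ratio.ndim else float(ratio)

    def pinning_ratio(self, w):
        """F_c / F_M: capillary pinning via the exposed contact perimeter."""
        w = np.asarray(w, dtype=float)
        d = self.cell_diameter
        exposed_perimeter = np.pi * d * np.clip(1.0 - w / d, 0.0, 1.0)
        f_c = self.pinning_strength * self.surface_tension * exposed_perimeter
        ratio = f_c / self.propulsion_force
        return ratio if ratio.ndim else float(ratio)

    def speed(self, w):
        """Swimming speed v(w), m/s, clamped at zero."""
        w = np.asarray(w, dtype=float)
        frac = 1.0 - self.drag_ratio(w) - self.pinning_ratio(w)
        v = self.v0 * np.clip(frac, 0.0, 1.0)
        return v if v.ndim else float(v)

    def threshold_film(self) -> float:
        """Film thickness at which v first becomes positive (v=0 below)."""
        a = self.cell_radius

        def f(w):
            return 1.0 - self.drag_ratio(w) - self.pinning_ratio(w)

        lo, hi = a * (1.0 + 1e-9), 1.0
        if f(hi) <= 0:
            return np.inf
        return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-14))


DEFAULT_FORCE_MODEL = ForceModel()


def swim_speed(w_eff, model: ForceModel = DEFAULT_FORCE_MODEL):
    """Swimming speed (m/s) for effective film thickness ``w_eff`` (m)."""
    return model.speed(w_eff)
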