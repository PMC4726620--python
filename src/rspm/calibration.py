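"""One-off calibration of the force model and chemotactic sensitivity.

Two printed anchors pin the drag law of :class:`~rspm.motility.ForceModel`:

1. mean swimming speed ~= 10 um/s at the wet limit (psi_m = -0.1 kPa) on the
   reference rough surface Phi = 0.4, D = 1.8, with v0 = 14 um/s;
2. swimming ceases (v = 0) at psi_m = -2 kPa on a surface with the
   domain-mean porosity Phi = 0.5 and D = 1.8.

Both anchors are evaluated through the patch-scale effective film thickness,
so the calibration is self-consistent with the retention model.  A third
anchor pins the chemotactic sensitivity chi_0: the analytic colony expansion
rate at psi_m = -0.5 kPa on the Phi_bar = 0.5 domain equals 500 um/hr.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .motility import ForceModel
from .surface import PhysicsConstants, RoughnessParams, effective_film_thickness

__all__ = ["calibrate_force_model", "calibrate_chemotactic_sensitivity"]

WET_ANCHOR_PSI = -0.1e3  # Pa, "very wet" end of the speed curve
WET_ANCHOR_SPEED = 10e-6  # m/s
DRY_ANCHOR_PSI = -2.0e3  # Pa, onset of capillary pinning at Phi=0.5
RATE_ANCHOR_PSI = -0.5e3  # Pa
RATE_ANCHOR = 500e-6 / 3600.0  # m/s, 500 um/hr


def calibrate_force_model(
    phys: PhysicsConstants = PhysicsConstants(),
    r_max: float = 1e-3,
    v0: float = 14e-6,
) -> ForceModel:
    """Solve (drag_coeff, drag_exponent) from the two printed speed anchors."""
    wet = RoughnessParams(Phi=0.4, D=1.8, r_max=r_max)
    dry = RoughnessParams(Phi=0.5, D=1.8, r_max=r_max)
    w_wet = effective_film_thickness(wet, WET_ANCHOR_PSI, phys)
    w_dry = effective_film_thickness(dry, DRY_ANCHOR_PSI, phys)

    base = ForceModel(v0=v0)
    a = base.cell_radius
    # In this film range (well above the cell diameter) pinning is zero, so
    # v/v0 = 1 - c * (a/(w-a))^n.  Two anchors give two equations:
    #   c * x_dry^n = 1            (v = 0 at w_dry)
    #   c * x_wet^n = 1 - v_wet/v0
    x_dry = a / (w_dry - a)
    x_wet = a / (w_wet - a)
    deficit = 1.0 - WET_ANCHOR_SPEED / v0
    n = float(np.log(deficit) / np.log(x_wet / x_dry))
    c = float(x_dry**-n)
    return ForceModel(v0=v0, drag_coeff=c, drag_exponent=n)


def calibrate_chemotactic_sensitivity(
    model: ForceModel,
    mu_max: float,
    growth_fraction: float,
    l_p: float = 5e-4,
    phys: PhysicsConstants = PhysicsConstants(),
    r_max: float = 1e-3,
) -> float:
    """chi_0 (m^2/s) such that the analytic expansion rate hits 500 um/hr.

    The reference chemotactic field is a one-patch-wide growth-rate front,
    |grad mu| = mu_max * growth_fraction / l_p, with growth_fraction =
    C0/(Ks + C0) at the scenario's boundary concentration.
    """
    from .analytics import retardation_factor
    from .connectivity import mean_field_local_connectivity

    dom = RoughnessParams(Phi=0.5, D=1.8, r_max=r_max)
    w = effective_film_thickness(dom, RATE_ANCHOR_PSI, phys)
    v = model.speed(w)
    if v <= 0:
        raise RuntimeError("force model gives v=0 at the rate anchor")
    xi = mean_field_local_connectivity(dom, RATE_ANCHOR_PSI, model, phys)
    target_rc = RATE_ANCHOR / (v * xi)
    if not 0 < target_rc < 1:
        raise RuntimeError("rate anchor unreachable: R_c out of (0,1)")
    x = brentq(lambda t: retardation_factor(t) - target_rc, 1e-12, 50.0)
    grad_mu = mu_max * growth_fraction / l_p
    return float(x * 2.0 * mu_max * v / grad_mu)
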