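"""Regenerate the calibrated motility constants.

Solves the drag-law constants of the force model from the two printed speed
anchors and the chemotactic sensitivity from the wet expansion-rate anchor,
then prints the values frozen in ``rspm.motility`` and ``rspm.ibm``.

Usage:  python scripts/calibrate_forces.py
"""

from rspm.calibration import (
    calibrate_chemotactic_sensitivity,
    calibrate_force_model,
)

MU_MAX_REF = 1.0 / 3600.0  # s^-1, reference species
GROWTH_FRACTION_REF = 0.5  # C0/(Ks + C0) at the dispersion boundary


def main() -> None:
    model = calibrate_force_model()
    chi0 = calibrate_chemotactic_sensitivity(
        model, MU_MAX_REF, GROWTH_FRACTION_REF
    )
    print(f"CAL_DRAG_COEFF = {model.drag_coeff:.7f}")
    print(f"CAL_DRAG_EXPONENT = {model.drag_exponent:.7f}")
    print(f"CAL_CHI0 = {chi0:.6e}")
    print(f"motility film threshold = {model.threshold_film() * 1e6:.3f} um")


if __name__ == "__main__":
    main()
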