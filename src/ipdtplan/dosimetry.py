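"""Whole-body photosensitizer dose arithmetic.

Links an injected dose (mg per kg body weight) to the expected tumor
tissue concentration given a fractional tumor uptake, assuming tissue
density 1 g/cm^3 so ug/g and ug/mL are interchangeable.
"""

from __future__ import annotations

__all__ = ["tumor_uptake_concentration"]


def tumor_uptake_concentration(
    injected_mg_per_kg: float,
    body_mass_g: float,
    uptake_fraction: float,
    tumor_mass_g: float = 1.0,
) -> float:
    """Tumor concentration in ug/g from a systemic injection.

    injected_total [ug] = dose [mg/kg] * body mass [kg] * 1000;
    concentration = uptake_fraction * injected_total / tumor mass.

    Example: 3% uptake of 10 mg/kg in a 200 g animal with a 1 g tumor
    gives 60 ug/g.
    """
    if injected_mg_per_kg < 0 or body_mass_g <= 0 or tumor_mass_g <= 0:
        raise ValueError("doses and masses must be positive")
    if not (0.0 <= uptake_fraction <= 1.0):
        raise ValueError("uptake_fraction must lie in [0, 1]")
    injected_ug = injected_mg_per_kg * (body_mass_g / 1000.0) * 1000.0
    return uptake_fraction * injected_ug / tumor_mass_g
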