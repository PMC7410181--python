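"""Stoichiometric and physiological constants of the fruit carbon balance.

All carbon bookkeeping is done in grams of carbon per fruit.  The three
conversion factors below translate between dry mass, sugar mass, starch mass
and carbon mass; the thermal-time base temperature is the lower development
threshold for tomato fruit.
"""

from __future__ import annotations

#: Conventional atomic masses (g mol^-1), sufficient precision for mass fractions.
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}


def carbon_mass_fraction(n_carbon: int, n_hydrogen: int, n_oxygen: int) -> float:
    """Carbon mass fraction of a C/H/O molecular (or repeat-unit) formula.

    ``carbon_mass_fraction(6, 12, 6)`` is the fraction for a hexose
    (glucose/fructose), ``carbon_mass_fraction(6, 10, 5)`` for the
    anhydroglucose repeat unit of starch.
    """
    mass = (
        n_carbon * ATOMIC_MASS["C"]
        + n_hydrogen * ATOMIC_MASS["H"]
        + n_oxygen * ATOMIC_MASS["O"]
    )
    return n_carbon * ATOMIC_MASS["C"] / mass


#: Carbon content of 1 g of fruit dry mass (g C g^-1 DW), tomato fruit.
C_DW = 0.44

#: Carbon content of 1 g of soluble sugars, from the hexose formula C6H12O6.
C_SOL = 0.4

#: Carbon content of 1 g of starch, from the (C6H10O5)n repeat unit.
C_STA = 0.444

#: Lower temperature threshold for tomato fruit development (degrees C).
T_BASE = 5.7
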