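"""Physical constants and unit conventions.

The package uses Å for lengths, ns for times and kcal/mol for energies
throughout.  Temperatures are in Kelvin.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: Default simulation temperature (K); kB*T = 0.596 kcal/mol.
DEFAULT_TEMPERATURE = 300.0

#: Atomic mass unit in grams.
AMU_TO_GRAM = 1.66053906660e-24

#: Cubic Ångström in cm³.
A3_TO_CM3 = 1e-24

#: Number density of bulk water at 1.0 g/cm³, molecules per Å³.
WATER_NUMBER_DENSITY = 1.0 / (18.01528 * AMU_TO_GRAM) * A3_TO_CM3


def kT(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol at ``temperature`` Kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
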