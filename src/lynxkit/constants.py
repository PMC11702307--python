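"""Physical constants and unit conventions.

Internal units throughout the package: force in pN, length in nm (Å for
atomic coordinates in :mod:`lynxkit.structure_tools`), rates in 1/s,
temperature in K.  Thermal energy kB·T is therefore in pN·nm.
"""

#: Boltzmann constant, pN·nm/K.
KB = 0.0138065

#: Default measurement temperature (25 °C), K.
DEFAULT_TEMPERATURE = 298.15


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB·T in pN·nm at the given absolute temperature."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
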