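"""Physical constants and unit conversions for the fixed internal unit system.

Internal units: nm, ps, kJ/mol, degrees, Kelvin.
"""

#: Boltzmann constant in kJ/(mol K) (i.e. the molar gas constant R).
KB_KJ_PER_MOL_K: float = 8.31446261815324e-3

#: nm^2/ps -> cm^2/s  (1 nm^2 = 1e-14 cm^2, 1 ps = 1e-12 s).
NM2_PER_PS_TO_CM2_PER_S: float = 1.0e-2

#: cm^2/s -> nm^2/ps.
CM2_PER_S_TO_NM2_PER_PS: float = 1.0e2

#: angstrom -> nm, used only at presentation boundaries.
ANGSTROM_TO_NM: float = 0.1


def thermal_energy(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol at the given temperature in K.

    At 323.15 K this is ~2.69 kJ/mol, the conventional "1 kBT ~ 2.7 kJ/mol"
    scale used when plotting reversible-work profiles in thermal units.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJ_PER_MOL_K * temperature
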