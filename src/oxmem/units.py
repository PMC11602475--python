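"""Unit system and physical constants.

Internal units everywhere: length nm, time ps, mass amu, energy kJ/mol,
temperature K. Readers convert on ingest; results carry explicit units in
their field names where they leave this system (e.g. diffusion coefficients
reported in um^2/s, permeability in cm/s).
"""

#: Ideal gas constant, kJ mol^-1 K^-1
R_KJ = 8.314e-3

#: amu / nm^3 -> kg / m^3
AMU_PER_NM3_TO_KG_M3 = 1.66053906892

#: um^2/s -> nm^2/ps
UM2_S_TO_NM2_PS = 1e-6

#: nm^2/ps -> um^2/s
NM2_PS_TO_UM2_S = 1e6

#: nm/ps -> cm/s
NM_PS_TO_CM_S = 1e5

#: cm^2/s -> nm^2/ps
CM2_S_TO_NM2_PS = 1e14 * 1e-12  # = 1e2


def kT(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol for a temperature in kelvin."""
    return R_KJ * temperature
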