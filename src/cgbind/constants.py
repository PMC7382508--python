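"""Physical constants and unit conventions.

Internal units throughout the package: length nm, time µs, energy kJ/mol,
temperature K.  Pose RMSDs are reported in Å (nm × 10) to match the
crystallographic convention; concentrations in mM unless stated otherwise.
"""

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462e-3

#: Default analysis temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Standard (1 M) number density, nm^-3.
C0_STANDARD = 1.0 / 1.66

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Water molecules represented by one coarse-grained water bead.
WATERS_PER_CG_BEAD = 4

#: Number density of liquid water at ~300 K, molecules nm^-3.
WATER_NUMBER_DENSITY = 33.37

#: Å per nm.
ANGSTROM_PER_NM = 10.0


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kJ/mol at the given temperature."""
    return R_GAS * temperature
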