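"""Physical constants and unit conversions.

Internal units throughout the package: kcal/mol (energy), Å (length),
ps (time), Da = g/mol (mass), K (temperature).  Force constants quoted
in kJ/mol/Å² (the umbrella-sampling convention) are converted on input.
"""

#: Boltzmann constant, kcal/mol/K
KB_KCAL = 0.0019872041

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184

#: 1 kcal/mol expressed in the mechanical internal unit Da·Å²/ps²
#: (1 Da·Å²/ps² = 10 J/mol, so 1 kcal/mol = 4184 J/mol = 418.4 Da·Å²/ps²)
KCAL_TO_DA_A2_PS2 = 418.4

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: 1 Da in kg
DA_TO_KG = 1.0 / (N_AVOGADRO * 1e3)

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 303.15


def kj_to_kcal(x: float) -> float:
    """Convert an energy (or force constant) from kJ/mol-based to kcal/mol-based units."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x: float) -> float:
    return x * KJ_PER_KCAL


def kBT(temperature: float) -> float:
    """Thermal energy in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature
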