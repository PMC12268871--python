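"""Internal unit system and physical constants.

Everything inside the package works in kJ/mol, nm, ps, K and elementary
charges (e); masses in unified atomic mass units (u).  Inputs given in
kcal/mol (a common convention for the repulsive amplitudes A and the
short-range constant B) are converted on read and the conversion logged.
"""

# Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145

# kJ per kcal
KCAL = 4.184

# Coulomb constant e^2/(4 pi eps0), kJ mol^-1 nm e^-2
KE = 138.935458

# fs -> ps
FS = 1.0e-3


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in (kJ/mol)^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)


def kcal_to_kj(x: float) -> float:
    return x * KCAL


def kj_to_kcal(x: float) -> float:
    return x / KCAL
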