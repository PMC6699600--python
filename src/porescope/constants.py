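"""Physical constants and unit conversions.

Internal length unit is the nanometre everywhere; PDB I/O converts
Angstrom <-> nm at the boundary.
"""

#: Boltzmann constant times Avogadro's number, kJ/(mol K).
KB_KJ_PER_MOL_K: float = 0.00831446261815324

#: Angstrom -> nanometre.
NM_PER_ANGSTROM: float = 0.1

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 298.15


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KJ_PER_MOL_K * temperature)
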