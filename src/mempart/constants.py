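"""Physical constants and unit conventions.

All reaction coordinates are in nm, energies in kJ/mol, force constants in
kJ mol^-1 nm^-2, temperatures in K and concentrations in uM throughout the
package; no unit auto-detection is performed.
"""

#: Molar gas constant in kJ mol^-1 K^-1 (CODATA 2018).
GAS_CONSTANT: float = 8.314462618e-3

#: Default physiological temperature in K.
DEFAULT_TEMPERATURE: float = 310.15


def rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kJ/mol at ``temperature`` (K).

    At the default 310.15 K this is 2.5787 kJ/mol.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT * temperature
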