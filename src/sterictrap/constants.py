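"""Physical constants and default temperatures.

Free energies are in kcal/mol throughout, concentrations in molar,
distances in Å, times in ns.
"""

#: Gas constant, kcal mol⁻¹ K⁻¹.
R_KCAL: float = 1.987e-3

#: Default temperature for experimental (titration) fits, K (25 °C).
T_EXPERIMENT: float = 298.15

#: Default temperature for simulation-derived energies, K (thermostat setpoint).
T_SIMULATION: float = 310.0


def rt(T: float = T_EXPERIMENT) -> float:
    """Thermal energy R·T in kcal/mol at absolute temperature ``T``.

    At 298.15 K this is 0.59248 kcal/mol, conventionally quoted as
    ~0.6 kcal/mol.
    """
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return R_KCAL * T
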