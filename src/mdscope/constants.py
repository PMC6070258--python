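"""Physical constants and simulation-wide defaults."""

#: molar gas constant, J/(mol K) — energies throughout are per mole
BOLTZMANN_J_PER_MOL_K = 8.31446261815324

#: simulation temperature (K) used for thermal mode amplitudes and landscapes
DEFAULT_TEMPERATURE_K = 303.0
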