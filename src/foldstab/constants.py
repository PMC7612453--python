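"""Physical constants used throughout the package.

All free energies are in kcal/mol and temperatures in absolute Kelvin, the
units of the NMR melting literature this package serves.
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.987e-3
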