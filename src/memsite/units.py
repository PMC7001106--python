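"""Unit conventions used throughout the package.

Everything internal is expressed in the units membrane simulation papers
report in: lengths in nanometres, times in nanoseconds, energies in
kJ/mol, temperatures in Kelvin.  File readers convert on the way in
(PDB Angstrom -> nm); writers convert on the way out where a format
demands it.
"""

#: Boltzmann constant in kJ/mol/K.
KB = 0.0083145

#: Default simulation temperature (K); all reweighting is done at this
#: temperature unless a caller overrides it.
DEFAULT_TEMPERATURE = 310.0


def kBT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    return KB * temperature
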