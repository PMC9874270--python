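"""Unit system and physical constants.

The package works in LAMMPS-style "real" units throughout:

* length   — ångström (Å)
* time     — femtosecond (fs)
* mass     — atomic mass unit (amu = g/mol)
* energy   — kcal/mol
* force    — kcal/mol/Å
* stress   — reported in MPa after conversion

The acceleration constant below follows from 1 kcal = 4184 J and
m[amu] = 1e-3/N_A kg: Avogadro's number cancels, so the value is exact.
"""

# Boltzmann constant, kcal mol^-1 K^-1 (R = 8.314462618 J mol^-1 K^-1 / 4184)
KB = 8.314462618 / 4184.0

# (kcal/mol/Å) / amu  ->  Å/fs^2
FORCE_TO_ACC = 4.184e-4

# 1 kcal mol^-1 Å^-3 -> MPa:  4184 J/mol / (N_A * 1e-30 m^3) / 1e6
AVOGADRO = 6.02214076e23
KCAL_PER_MOL_A3_TO_MPA = 4184.0 / (AVOGADRO * 1e-30) / 1e6  # ~6947.7 MPa

# 1 Å/fs = 1e5 m/s
A_PER_FS_TO_M_PER_S = 1e5

# strain rate: s^-1 -> fs^-1
PER_S_TO_PER_FS = 1e-15
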