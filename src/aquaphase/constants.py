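"""Physical constants and unit conversions.

Internal units are fixed throughout the package: lengths in Å,
temperatures in K, pressures in bar, densities in g/L, molar energies
in kJ/mol.  Conversions happen only at I/O boundaries.
"""

#: Avogadro constant [1/mol]
N_AVOGADRO = 6.02214076e23

#: Molar mass of water [g/mol]
M_WATER = 18.0153

#: Gas constant [L bar / (mol K)]
R_LBAR = 0.0831446

#: 1 L·bar in kJ
LBAR_TO_KJ = 0.1

#: 1 e·Å in Debye (elementary charge times Ångström, CODATA-derived)
EA_TO_DEBYE = 4.80320

#: 1 Å^3 in L
A3_TO_L = 1.0e-27

#: nm -> Å
NM_TO_A = 10.0

#: kcal -> kJ
KCAL_TO_KJ = 4.184
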