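"""Physical constants in the kcal/mol, Angstrom, elementary-charge unit system.

The Coulomb constant is fixed at the value used by classic liquid-state
simulation codes so that golden values reproduce bit-for-bit; it is *not*
the CODATA value rounded.
"""

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_KCAL = 332.06

#: Boltzmann constant, kcal/(mol*K).
BOLTZMANN_KCAL = 0.0019872041

#: Pressure-volume conversion: 1 atm*A^3 per molecule -> kcal/mol.
ATM_A3_TO_KCAL = 1.4584e-5

#: 1 cm^3*atm = 0.024217 cal exactly (documented conversion for excess-volume
#: reference lines); expressed here in kcal per (cm^3/mol * atm).
CM3_ATM_TO_KCAL = 0.024217e-3
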