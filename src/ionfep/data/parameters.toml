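# Force-field parameters for rigid 4-site water and monoatomic ions.
#
# Water: TIP4P (Jorgensen et al., J. Chem. Phys. 79, 926 (1983)).
# Ions:  Lennard-Jones parameters of Jensen & Jorgensen
#        (J. Chem. Theory Comput. 2, 1499 (2006)), fitted for use with
#        TIP4P water and geometric-mean combining rules.
#
# Units: Angstrom, kcal/mol, elementary charge, degrees.

[water.tip4p]
sigma_O = 3.15365
epsilon_O = 0.1550
q_H = 0.52
q_M = -1.04
r_OH = 0.9572
theta_HOH = 104.52
r_OM = 0.15

[ions.K]
charge = 1
sigma = 5.17
epsilon = 0.0005

[ions.Rb]
charge = 1
sigma = 5.60
epsilon = 0.0005

[ions.Cs]
charge = 1
sigma = 6.20
epsilon = 0.0005

[ions.Br]
charge = -1
sigma = 4.28
epsilon = 0.71

[ions.I]
charge = -1
sigma = 4.81
epsilon = 0.71
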