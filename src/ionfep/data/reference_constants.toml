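# Reference constants used by the analysis layer. These are *inputs* of the
# discrepancy ledgers and comparison plots, never outputs of any computation.
#
# dG_hyd_exp: experimental single-ion hydration free energies (kcal/mol) on
#   the Marcus scale (Marcus, "Ion Solvation", and the derived compilation
#   used as the fitting target of the Jensen-Jorgensen ion parameters).
# phi: air/water interface potential of TIP4P water, kcal/(mol*e).
# v_star: excess volumes (cm^3/mol). NOTE: the excess-volume and KB_II
#   entries below are approximate literature-derived placeholders meant for
#   illustrative reference lines; replace them with your preferred
#   compilation before drawing quantitative conclusions.

phi = -14.53  # kcal/(mol*e), TIP4P air/water interface potential

[dG_hyd_exp]
K = -70.5
Rb = -65.7
Cs = -59.8
Br = -75.3
I = -65.7

[v_star]
K = 10.1
Rb = 15.2
Cs = 22.4
Br = 23.6
I = 35.1

[kb_ii]
K = 14.0
Rb = 19.0
Cs = 26.0
Br = 28.0
I = 41.0
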