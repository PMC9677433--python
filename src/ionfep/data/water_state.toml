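# Thermodynamic state data for liquid water at 298.15 K along the isotherm.
#
# eps_r: experimental static dielectric constant. Values at 1, 4000 and 8000
#   atm follow the experimental compilation for water at 298.15 K; values at
#   intermediate pressures are smooth interpolations and may be overridden
#   in a run configuration.
# rho_rel: number density relative to 1 atm (approximate liquid-water
#   compression at 298.15 K); used by the density-scaled boundary-artifact
#   correction. rho_1atm is the TIP4P number density at ambient conditions.
#
# All entries are configuration data, user-overridable; none is computed.

rho_1atm = 0.03303  # molecules/A^3 (TIP4P, 0.988 g/cm^3 at 298.15 K, 1 atm)

[[state]]
P = 1
eps_r = 78.4
rho_rel = 1.000

[[state]]
P = 1000
eps_r = 81.8
rho_rel = 1.041

[[state]]
P = 2000
eps_r = 85.0
rho_rel = 1.077

[[state]]
P = 3000
eps_r = 88.1
rho_rel = 1.108

[[state]]
P = 4000
eps_r = 91.1
rho_rel = 1.136

[[state]]
P = 6000
eps_r = 94.9
rho_rel = 1.184

[[state]]
P = 8000
eps_r = 98.5
rho_rel = 1.225
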