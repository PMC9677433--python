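# ionfep

Chemical potentials of monoatomic ions (K⁺, Rb⁺, Cs⁺, Br⁻, I⁻) in water
under pressure, from NPT Metropolis Monte Carlo with free-energy
perturbation, together with continuum-electrostatics corrections for the
systematic errors introduced by sharp molecular potential truncation
(MPT).  It is written for molecular-simulation practitioners who compute
ion hydration free energies with truncated (non-Ewald) electrostatics and
need the correction machinery, and for anyone studying how the hydrophobic
and hydrophilic components of ion hydration respond to compression.

## The model

The chemical potential (Ben-Naim convention, equal to the hydration free
energy Δ_hyd G*) is decomposed into two FEP legs,

    μ* = ΔG(0 → LJ) + ΔG(LJ → LJ + q),

sampled by Metropolis NPT Monte Carlo of one ion fixed at the center of a
cubic periodic box of rigid TIP4P waters, with geometric-mean combining
and sharp molecule-based cutoffs (production: R_IW = R_WW = 11.5 Å).
Each leg runs in double-wide windows: the reference simulation at λ_ref
yields Zwanzig estimates −kT ln⟨exp(−βΔE)⟩ toward both λ_ref ± Δλ, with
block-average uncertainties and a Friedberg–Cameron statistical-
inefficiency diagnostic for the correlation time.

Truncation corrections, all formulated in a continuum dielectric:

* **C_LR** — Born energy −(k_C q²/2R_LR)(1 − 1/ε_r) of the dielectric
  beyond R_LR = R_IW + δ (default δ = 1.7 Å, one water shell).
* **C_WW** — water–water truncation error, from an apparent-surface-charge
  Poisson solver: the cavity charging free energy ΔG_q is computed from
  1000 surface point charges with and without a cutoff applied to the
  inter-charge interaction matrix **T**; C_WW = ΔG_q − ΔG_q^cut > 0.
  A windowed discrete-charging form gives the correction at intermediate
  coupled charge.
* **−Aq** — boundary-artifact correction from the static potential A, the
  linear coefficient of the quadratic charge-scaling fit
  ΔG = A(λq) + B(λq)².
* **C_BA** — alternative boundary-artifact correction proportional to the
  water number density, anchored so the corrected 1-atm result matches the
  experimental reference.

The analysis layer assembles C₁ = C_LR + C_WW, C₂ = C₁ + C_BA,
C₃ = C₁ − Aq, discrepancy ledgers against the Marcus experimental
compilation, ion differences, electrolyte sums, and pressure profiles
Δμ*(P) with excess-volume reference lines.

See `docs/methods.md` for assumptions, numerical choices (including the
two diagonal closures of the surface-charge matrix and why they matter at
the 0.2 kcal/mol level), and limitations.

## Worked example

```python
import ionfep as f

m = f.DielectricMedium(78.4, pressure=1.0)       # water at 298.15 K, 1 atm
clr = f.c_lr(1.0, 11.5, m)                       # Born beyond R_LR = 13.2 A
cww = f.c_ww(13.2, m, 11.5)                      # T-matrix cutoff at 11.5 A
print(f"C_LR = {clr:.2f}  C_WW = {cww:.2f}  C_1 = {clr + cww:.2f}")

res = f.IonResult(ion="K", charge=1, pressure=1.0, dg_lj=5.37, dg_q=-76.3)
ref = f.ReferenceConstants(dg_hyd_exp={"K": -70.5}, phi=-14.53)
row = f.discrepancy_ledger(res, clr, cww, ref, A=-13.2)
print({k: round(v, 1) for k, v in row.items() if k.startswith("dDG")})
```

prints

```
C_LR = -12.42  C_WW = 5.00  C_1 = -7.42
{'dDG1': -0.4, 'dDG2': -12.8, 'dDG3': -7.8, 'dDG3_minus_Phi_q': 6.7, 'dDG3_minus_Aq': 5.4}
```

C_LR restores the −12.42 kcal/mol of polarization the 11.5 Å ion–water
cutoff discards; the water–water cutoff error partially cancels it
(C_WW = +5.0), leaving a net −7.4.  For K⁺ the raw FEP estimate of μ*
(5.37 − 76.3 = −70.9 kcal/mol) sits only 0.4 below the experimental
−70.5 (`dDG1`); after both corrections the residual `dDG3` = −7.8 is the
cation-side boundary artifact, which the static-potential column
(`dDG3_minus_Aq`) largely removes.

The same tables are available from the shell:

```
$ ionfep corrections -r 13.2 -r 10.0 -c 10.0 -c 11.5
R_LR    C_WW(10)  C_WW(11.5)  C_LR    C_LR+C_WW
13.2    5.73      5.0         -12.42  -7.42
10.0    5.61      4.53        -16.39  -11.86
```

Other subcommands: `simulate` (NPT MC with XYZ/JSON checkpointing),
`fep` (a desk-scale charging or LJ leg), `tau` (correlation-time
diagnostics), `fit` (charge-scaling fit), `report` (discrepancy ledger),
`fixtures` (synthetic inputs).  A desk-scale charging leg for K⁺
(64 waters, 10 windows, 10⁵ averaging trials per window, ~2 min) gives
ΔG(LJ → LJ+q) = −75.1 ± 0.5 kcal/mol.

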