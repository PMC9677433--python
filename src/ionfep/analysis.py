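"""Result assembly: charge-scaling fits, discrepancy ledgers, ion
differences, electrolyte sums, and pressure profiles.

The charging free energy of a monovalent ion is, to good accuracy,
quadratic in the coupled charge,

    dG(LJ -> LJ + lambda q) = A (lambda q) + B (lambda q)^2,

with zero intercept (at lambda = 0 nothing has been charged yet).  The
linear coefficient A is the static electrostatic potential felt by the
solute charge; it is attractive for cations and repulsive for anions and
is dominated by water orientations near the truncation boundary, so -Aq
serves as a boundary-artifact correction.  A is well defined when fitted
at small coupling and noticeably less so near full coupling, which is why
fits over restricted intervals carry diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import CM3_ATM_TO_KCAL

__all__ = [
    "ChargingCurve",
    "QuadraticFit",
    "IonResult",
    "ReferenceConstants",
    "fit_charging_curve",
    "discrepancy_ledger",
    "ion_difference",
    "electrolyte_sum",
    "pressure_profile",
    "excess_volume_line",
]


@dataclass
class ChargingCurve:
    """dG(LJ -> LJ + lambda q) versus the coupled charge lambda*q."""

    lam_q: np.ndarray  # coupled charge values (e), strictly increasing in |q|
    dg: np.ndarray  # kcal/mol
    sigma: np.ndarray | None = None  # uncertainties, kcal/mol
    ion: str = ""
    pressure: float = 1.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        self.lam_q = np.asarray(self.lam_q, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(np.abs(self.lam_q)) <= 0):
            raise ValueError("coupled charge must be strictly increasing in magnitude")


@dataclass(frozen=True)
class QuadraticFit:
    """Zero-intercept weighted fit dG = A x + B x^2, x = lambda q."""

    A: float  # kcal/(mol e): static electrostatic potential
    B: float  # kcal/(mol e^2)
    covariance: np.ndarray
    interval: tuple[float, float]
    residuals: np.ndarray
    n_points: int

    @property
    def A_err(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def B_err(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.A * x + self.B * x * x


@dataclass
class IonResult:
    """FEP components and corrected chemical potentials for one ion/pressure."""

    ion: str
    charge: float  # signed, e
    pressure: float
    dg_lj: float
    dg_q: float
    dg_lj_err: float = 0.0
    dg_q_err: float = 0.0

    @property
    def mu_star(self) -> float:
        return self.dg_lj + self.dg_q

    @property
    def mu_star_err(self) -> float:
        return float(np.hypot(self.dg_lj_err, self.dg_q_err))

    def corrected(self, correction: float) -> float:
        return self.mu_star + correction


@dataclass
class ReferenceConstants:
    """Experimental reference data: inputs, never computed."""

    dg_hyd_exp: dict  # kcal/mol per ion, Marcus scale
    phi: float  # air/water interface potential, kcal/(mol e)
    v_star: dict = field(default_factory=dict)  # cm^3/mol
    kb_ii: dict = field(default_factory=dict)  # cm^3/mol


# --------------------------------------------------------------------------
# charge-scaling fit
# --------------------------------------------------------------------------

def fit_charging_curve(
    curve: ChargingCurve,
    interval: tuple[float, float] | None = None,
) -> QuadraticFit:
    """Weighted least squares of dG = A(lambda q) + B(lambda q)^2.

    ``interval`` restricts the fit to |lambda| in [lo, hi] (the coupling
    fraction, not the charge); weights are 1/sigma^2 when uncertainties
    are present.  At least 3 points are required.
    """
    x = curve.lam_q
    y = curve.dg
    q_full = x[np.argmax(np.abs(x))]
    lam = np.abs(x / q_full) if q_full != 0 else np.abs(x)
    if interval is None:
        sel = np.ones_like(x, dtype=bool)
        interval = (0.0, 1.0)
    else:
        lo, hi = interval
        sel = (lam >= lo - 1e-12) & (lam <= hi + 1e-12)
    if sel.sum() < 3:
        raise ValueError("need at least 3 points inside the fit interval")
    xs, ys = x[sel], y[sel]
    if curve.sigma is not None:
        w = 1.0 / curve.sigma[sel] ** 2
    else:
        w = np.ones_like(xs)
    design = np.stack([xs, xs * xs], axis=1)
    wd = design * np.sqrt(w)[:, None]
    wy = ys * np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(wd, wy, rcond=None)
    if rank < 2:
        raise ValueError("singular design matrix")
    resid = ys - design @ coef
    dof = max(len(xs) - 2, 1)
    if curve.sigma is not None:
        cov = np.linalg.inv(design.T @ (design * w[:, None]))
    else:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
    return QuadraticFit(
        A=float(coef[0]),
        B=float(coef[1]),
        covariance=cov,
        interval=tuple(interval),
        residuals=resid,
        n_points=int(sel.sum()),
    )


# --------------------------------------------------------------------------
# ledgers and combinations
# --------------------------------------------------------------------------

def discrepancy_ledger(
    result: IonResult,
    c_lr: float,
    c_ww: float,
    reference: ReferenceConstants,
    *,
    A: float | None = None,
) -> dict:
    """Discrepancies against the experimental hydration free energy.

    dDG1 = mu*_FEP - dG_exp; dDG2 = dDG1 + C_LR; dDG3 = dDG2 + C_WW.
    The Aq and Phi*q columns use the signed ion charge, so flipping the
    charge sign flips their sign with all else fixed.
    """
    exp = reference.dg_hyd_exp[result.ion]
    d1 = result.mu_star - exp
    d2 = d1 + c_lr
    d3 = d2 + c_ww
    row = {
        "ion": result.ion,
        "dG_hyd_exp": exp,
        "dDG1": d1,
        "dDG2": d2,
        "dDG3": d3,
        "dDG3_minus_Phi_q": d3 - reference.phi * result.charge,
    }
    if A is not None:
        row["dDG3_minus_Aq"] = d3 - A * result.charge
    return row


def ion_difference(a: IonResult, b: IonResult) -> tuple[float, float]:
    """mu*(a) - mu*(b) with quadrature-propagated uncertainty.

    Geometry-independent corrections (C_LR, C_WW) cancel between ions of
    equal |q|, so the raw FEP difference is also the corrected one.
    """
    return a.mu_star - b.mu_star, float(np.hypot(a.mu_star_err, b.mu_star_err))


def electrolyte_sum(
    cation: IonResult,
    anion: IonResult,
    *,
    correction_cation: float = 0.0,
    correction_anion: float = 0.0,
) -> tuple[float, float]:
    """Hydration free energy of the electrolyte (cation + anion).

    The same correction *set* must be applied to both ions; charge-odd
    terms (Aq, Phi q, the sign of C_BA) then cancel or combine through the
    signed charges.
    """
    if cation.charge <= 0 or anion.charge >= 0:
        raise ValueError("expected a (cation, anion) pair")
    total = cation.corrected(correction_cation) + anion.corrected(correction_anion)
    err = float(np.hypot(cation.mu_star_err, anion.mu_star_err))
    return total, err


def pressure_profile(pressures, mu_values) -> tuple[np.ndarray, CubicSpline]:
    """d_mu*(P) = mu*(P) - mu*(1 atm) and a natural cubic-spline interpolant.

    The profile is exactly zero at the lowest pressure (taken as the 1 atm
    reference); the spline passes through every computed point.
    """
    p = np.asarray(pressures, dtype=float)
    mu = np.asarray(mu_values, dtype=float)
    order = np.argsort(p)
    p, mu = p[order], mu[order]
    delta = mu - mu[0]
    spline = CubicSpline(p, delta, bc_type="natural")
    return delta, spline


def excess_volume_line(v_star: float, pressures) -> np.ndarray:
    """Linear reference d_mu* = (P - 1 atm) * v* converted to kcal/mol.

    v* in cm^3/mol, pressures in atm; 1 cm^3 atm = 0.024217 cal exactly.
    """
    p = np.asarray(pressures, dtype=float)
    return (p - 1.0) * v_star * CM3_ATM_TO_KCAL
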