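"""Free-energy perturbation: Zwanzig averaging, double-wide windows,
block statistics and correlation-time diagnostics.

A free-energy difference between a reference state (0) and a nearby
perturbed state (1) is estimated by exponential averaging over the
reference ensemble,

    dG = -(1/beta) ln < exp(-beta dE) >_0 ,    dE = E1 - E0,

evaluated at the sampled configurations *and volume* of the reference
state; in NPT the PV terms of the two states then cancel identically, so
the same formula yields a Gibbs free energy.  A full coupling process is
split into windows tiling lambda in [0, 1]; each reference simulation at
lambda_i0 is perturbed toward both lambda_i0 - dlam and lambda_i0 + dlam
(double-wide sampling), so one run yields two estimates.

Default schedules mirror the production setup this package is built
around: 10 double-wide windows for the charging leg (increments of 0.05 in
the coupled charge) and 5 windows for Lennard-Jones annihilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import logsumexp

from .forcefield import Configuration, CouplingState, CutoffScheme, IonSpec, ion_water_energy
from .mc import MoveSettings, NptMonteCarlo, ThermoState

__all__ = [
    "Window",
    "WindowResult",
    "WindowSum",
    "FreeEnergyComponent",
    "zwanzig_estimate",
    "default_charge_schedule",
    "default_lj_schedule",
    "double_wide_window",
    "sum_windows",
    "statistical_inefficiency",
    "fit_correlation_time",
    "simulate_window",
    "run_leg",
]


# --------------------------------------------------------------------------
# types and schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """One double-wide window: reference lambda_ref, increments +-delta."""

    lambda_ref: float
    delta: float
    kind: str = "charge"  # which interaction is scaled: "charge" or "lj"

    def __post_init__(self) -> None:
        if self.kind not in ("charge", "lj"):
            raise ValueError("window kind must be 'charge' or 'lj'")
        lo, hi = self.lambda_ref - self.delta, self.lambda_ref + self.delta
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"window [{lo}, {hi}] leaves the coupling range [0, 1]")


@dataclass
class WindowResult:
    """Double-wide estimates of one window with block statistics.

    ``dg_down``/``dg_up`` are dG(lambda_ref -> lambda_ref -+ delta) from the
    pooled samples; ``blocks_down``/``blocks_up`` hold per-block values.
    """

    window: Window
    dg_down: float
    dg_up: float
    blocks_down: np.ndarray
    blocks_up: np.ndarray
    block_trials: int

    @property
    def stderr_down(self) -> float:
        return _block_stderr(self.blocks_down)

    @property
    def stderr_up(self) -> float:
        return _block_stderr(self.blocks_up)


@dataclass(frozen=True)
class WindowSum:
    """Signed total over a window tiling, with quadrature uncertainty."""

    value: float
    stderr: float
    direction: str  # "coupling" (0 -> 1) or "decoupling" (1 -> 0)


@dataclass
class FreeEnergyComponent:
    """dG(0 -> LJ), dG(LJ -> LJ+q) and their sum mu* (kcal/mol)."""

    dg_lj: float
    dg_lj_err: float
    dg_q: float
    dg_q_err: float

    @property
    def mu_star(self) -> float:
        return self.dg_lj + self.dg_q

    @property
    def mu_star_err(self) -> float:
        return float(np.hypot(self.dg_lj_err, self.dg_q_err))


def _block_stderr(blocks: np.ndarray) -> float:
    blocks = np.asarray(blocks, dtype=float)
    if len(blocks) < 2:
        return float("nan")
    return float(np.std(blocks, ddof=1) / np.sqrt(len(blocks)))


def _tiling_schedule(n_windows: int, kind: str) -> list[Window]:
    delta = 1.0 / (2 * n_windows)
    return [
        Window(lambda_ref=(2 * i + 1) * delta, delta=delta, kind=kind)
        for i in range(n_windows)
    ]


def default_charge_schedule(n_windows: int = 10) -> list[Window]:
    """10 double-wide windows: charge increments of 0.05 for a unit ion."""
    return _tiling_schedule(n_windows, "charge")


def default_lj_schedule(n_windows: int = 5) -> list[Window]:
    """5 double-wide windows for LJ annihilation."""
    return _tiling_schedule(n_windows, "lj")


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def zwanzig_estimate(delta_e, beta: float) -> float:
    """Exponential-average free energy, log-sum-exp stabilized.

    ``delta_e`` are perturbation energies E(perturbed) - E(reference) on
    reference-ensemble configurations, kcal/mol.
    """
    delta_e = np.asarray(delta_e, dtype=float)
    if delta_e.size == 0:
        raise ValueError("empty perturbation-energy sample")
    return float(
        -(logsumexp(-beta * delta_e) - np.log(delta_e.size)) / beta
    )


def double_wide_window(
    window: Window,
    de_down: np.ndarray,
    de_up: np.ndarray,
    beta: float,
    *,
    n_blocks: int = 10,
    block_trials: int | None = None,
) -> WindowResult:
    """Turn collected perturbation energies into a double-wide result.

    The pooled Zwanzig estimate is reported alongside per-block values;
    block boundaries simply partition the sample streams in order.
    """
    de_down = np.asarray(de_down, dtype=float)
    de_up = np.asarray(de_up, dtype=float)
    blocks_down = [zwanzig_estimate(b, beta) for b in np.array_split(de_down, n_blocks) if b.size]
    blocks_up = [zwanzig_estimate(b, beta) for b in np.array_split(de_up, n_blocks) if b.size]
    return WindowResult(
        window=window,
        dg_down=zwanzig_estimate(de_down, beta),
        dg_up=zwanzig_estimate(de_up, beta),
        blocks_down=np.array(blocks_down),
        blocks_up=np.array(blocks_up),
        block_trials=block_trials or 0,
    )


def sum_windows(results: list[WindowResult], *, direction: str = "coupling") -> WindowSum:
    """Signed sum over a tiling of [0, 1].

    Going upward through window i contributes dg_up - dg_down (the segment
    lambda_ref - delta -> lambda_ref + delta); ``direction="decoupling"``
    negates the total.  Window uncertainties combine in quadrature,
    assuming independently run windows.
    """
    if direction not in ("coupling", "decoupling"):
        raise ValueError("direction must be 'coupling' or 'decoupling'")
    ordered = sorted(results, key=lambda r: r.window.lambda_ref)
    _check_tiling(ordered)
    total = sum(r.dg_up - r.dg_down for r in ordered)
    var = sum(
        (0.0 if np.isnan(r.stderr_up) else r.stderr_up ** 2)
        + (0.0 if np.isnan(r.stderr_down) else r.stderr_down ** 2)
        for r in ordered
    )
    if direction == "decoupling":
        total = -total
    return WindowSum(value=float(total), stderr=float(np.sqrt(var)), direction=direction)


def _check_tiling(ordered: list[WindowResult]) -> None:
    prev_hi = 0.0
    for r in ordered:
        lo = r.window.lambda_ref - r.window.delta
        if abs(lo - prev_hi) > 1e-9:
            raise ValueError("windows do not tile [0, 1] without gaps")
        prev_hi = r.window.lambda_ref + r.window.delta
    if abs(prev_hi - 1.0) > 1e-9:
        raise ValueError("windows do not tile [0, 1] without gaps")


# --------------------------------------------------------------------------
# correlation diagnostics
# --------------------------------------------------------------------------

def statistical_inefficiency(series, block_sizes) -> np.ndarray:
    """s(n_t) = n_t * var(block means) / var(series) for each block size.

    Block sizes must divide the series length and leave at least 2 blocks.
    A constant series has zero variance and is flagged as degenerate.
    """
    x = np.asarray(series, dtype=float)
    var = np.var(x)
    if var == 0:
        raise ValueError("degenerate series: zero variance")
    out = []
    for n_t in np.atleast_1d(block_sizes):
        n_t = int(n_t)
        if len(x) % n_t != 0:
            raise ValueError(f"block size {n_t} does not divide series length {len(x)}")
        n_blocks = len(x) // n_t
        if n_blocks < 2:
            raise ValueError(f"fewer than 2 blocks at block size {n_t}")
        means = x.reshape(n_blocks, n_t).mean(axis=1)
        out.append(n_t * np.var(means) / var)
    return np.array(out)


def fit_correlation_time(block_sizes, s_values) -> tuple[float, float]:
    """Plateau of s versus sqrt(n_t) by nonlinear regression.

    The fitted form is s(n_t) = tau * (1 - a / sqrt(n_t)); the plateau tau
    estimates the correlation "time" (in trials) between configurations.
    Returns (tau_corr, a).
    """
    n_t = np.asarray(block_sizes, dtype=float)
    s = np.asarray(s_values, dtype=float)

    def model(n, tau, a):
        return tau * (1 - a / np.sqrt(n))

    p0 = (max(s[-1], 1.0), 1.0)
    popt, _ = curve_fit(model, n_t, s, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1])


# --------------------------------------------------------------------------
# simulation drivers
# --------------------------------------------------------------------------

def _coupling_for(window: Window, lam: float) -> CouplingState:
    if window.kind == "charge":
        return CouplingState(lambda_lj=1.0, lambda_q=lam)
    return CouplingState(lambda_lj=lam, lambda_q=0.0)


def simulate_window(
    window: Window,
    config: Configuration,
    thermo: ThermoState,
    settings: MoveSettings,
    ion: IonSpec,
    cutoffs: CutoffScheme,
    *,
    n_equil: int = 20_000,
    n_avg: int = 100_000,
    stride: int = 20,
    n_blocks: int = 10,
) -> tuple[WindowResult, Configuration]:
    """Run the reference simulation of one window and collect both
    double-wide perturbation energies.

    Returns the window result and the final configuration (handed to the
    next window so the schedule walks through coupling space).
    """
    ref = _coupling_for(window, window.lambda_ref)
    lam_dn = window.lambda_ref - window.delta
    lam_up = window.lambda_ref + window.delta
    engine = NptMonteCarlo(config, thermo, settings, ion, ref, cutoffs)
    engine.equilibrate(n_equil)

    de_down: list[float] = []
    de_up: list[float] = []

    if window.kind == "charge":
        # the Coulomb term is exactly linear in lambda_q: one evaluation of
        # the unit-charge ion-water Coulomb energy gives both perturbations
        unit = CouplingState(lambda_lj=0.0, lambda_q=1.0)

        def observer(eng: NptMonteCarlo) -> None:
            u_coul = ion_water_energy(eng.config, ion, unit, cutoffs)
            de_down.append((lam_dn - window.lambda_ref) * u_coul)
            de_up.append((lam_up - window.lambda_ref) * u_coul)

    else:
        cpl_dn = _coupling_for(window, lam_dn)
        cpl_up = _coupling_for(window, lam_up)
        lj_only = CouplingState(lambda_lj=window.lambda_ref, lambda_q=0.0)

        def observer(eng: NptMonteCarlo) -> None:
            u_ref = ion_water_energy(eng.config, ion, lj_only, cutoffs)
            de_down.append(ion_water_energy(eng.config, ion, cpl_dn, cutoffs) - u_ref)
            de_up.append(ion_water_energy(eng.config, ion, cpl_up, cutoffs) - u_ref)

    engine.run(n_avg, observer=observer, stride=stride)
    result = double_wide_window(
        window,
        np.array(de_down),
        np.array(de_up),
        thermo.beta,
        n_blocks=n_blocks,
        block_trials=n_avg // n_blocks,
    )
    return result, engine.config


def run_leg(
    schedule: list[Window],
    config: Configuration,
    thermo: ThermoState,
    settings: MoveSettings,
    ion: IonSpec,
    cutoffs: CutoffScheme,
    **window_kwargs,
) -> tuple[WindowSum, list[WindowResult]]:
    """Run every window of a schedule in sequence and sum the tiling."""
    results = []
    current = config
    for window in schedule:
        res, current = simulate_window(
            window, current, thermo, settings, ion, cutoffs, **window_kwargs
        )
        results.append(res)
    return sum_windows(results), results
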