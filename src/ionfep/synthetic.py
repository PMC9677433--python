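"""Synthetic inputs: water boxes, charging curves, and correlated series.

Everything here is deterministic per seed.  The water-box generator places
rigid molecules at a requested number density with uniformly random
orientations, rejecting hard overlaps; it emulates a pre-equilibrated
liquid only in density, not in structure, so fresh boxes need Monte Carlo
equilibration before averaging.
"""

from __future__ import annotations

import numpy as np

from .analysis import ChargingCurve
from .forcefield import Configuration, WaterModel, load_water_model

__all__ = [
    "generate_water_box",
    "generate_synthetic_charging_curve",
    "generate_ar1_series",
    "random_quaternions",
]


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations (Shoemake's method), as (w, x, y, z)."""
    u1, u2, u3 = rng.random((3, n))
    q = np.stack(
        [
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
        ],
        axis=1,
    )
    return q


def generate_water_box(
    n_waters: int,
    density: float = 0.03303,
    seed: int = 0,
    *,
    model: WaterModel | None = None,
    min_oo: float = 2.4,
    min_ion_o: float = 2.8,
    max_attempts: int = 200_000,
) -> Configuration:
    """Random non-overlapping water box at exactly the requested density.

    ``density`` is the water number density (molecules/A^3); the box length
    is L = (N / density)^(1/3), so the realized density is exact by
    construction.  The ion site at the box center is kept clear by
    ``min_ion_o``.  N = 0 gives an ion-only box of 10 A.
    """
    if model is None:
        model = load_water_model()
    rng = np.random.default_rng(seed)
    if n_waters == 0:
        return Configuration(
            box_length=10.0,
            positions=np.zeros((0, 3)),
            orientations=np.zeros((0, 4)),
            model=model,
        )
    L = (n_waters / density) ** (1.0 / 3.0)
    center = np.full(3, L / 2)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n_waters:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_waters} waters at density {density} "
                f"(min O-O {min_oo} A)"
            )
        trial = rng.random(3) * L
        d_ion = trial - center
        d_ion -= L * np.round(d_ion / L)
        if np.linalg.norm(d_ion) < min_ion_o:
            continue
        ok = True
        for p in positions:
            d = trial - p
            d -= L * np.round(d / L)
            if d @ d < min_oo * min_oo:
                ok = False
                break
        if ok:
            positions.append(trial)
    return Configuration(
        box_length=L,
        positions=np.array(positions),
        orientations=random_quaternions(n_waters, rng),
        model=model,
    )


def generate_synthetic_charging_curve(
    A: float,
    B: float,
    lam_grid,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    q: float = 1.0,
    ion: str = "synthetic",
) -> tuple[ChargingCurve, dict]:
    """Quadratic charging curve dG = A x + B x^2 (+ Gaussian noise), x = lam*q.

    Returns the curve and the ground truth used to generate it, for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(lam_grid, dtype=float) * q
    dg = A * x + B * x * x
    sigma = None
    if noise_sigma > 0:
        dg = dg + rng.normal(0.0, noise_sigma, size=len(x))
        sigma = np.full(len(x), noise_sigma)
    curve = ChargingCurve(lam_q=x, dg=dg, sigma=sigma, ion=ion)
    return curve, {"A": A, "B": B, "noise_sigma": noise_sigma, "seed": seed}


def generate_ar1_series(phi: float, n: int, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + e_t, unit innovations.

    Its statistical inefficiency plateaus at (1 + phi)/(1 - phi).
    """
    if not -1 < phi < 1:
        raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    eps = rng.normal(size=n)
    x0 = rng.normal() / np.sqrt(1 - phi * phi)  # stationary start
    x, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return x
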