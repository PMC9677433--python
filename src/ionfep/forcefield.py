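"""Molecular models and truncated interaction energies.

The system is one monoatomic ion held fixed at the center of a cubic
periodic box of rigid 4-site waters.  Water-water interactions are a single
Lennard-Jones site on oxygen plus Coulomb interactions between the three
charged sites (H, H, M); the ion carries a point charge and an LJ site.

Truncation is sharp and molecule-based: a pair of waters interacts in full
if their minimum-image O-O distance is below the water-water cutoff and not
at all otherwise; a water interacts with the ion if its minimum-image ion-O
distance is below the ion-water cutoff.  There is no switching function and
no long-range LJ tail correction -- the point of this package is to study
(and correct for) exactly this kind of truncation.

Combining rules are geometric mean for both sigma and epsilon (the OPLS
convention).  Alchemical coupling scales the ion parameters linearly:
charge by lambda_q, and both LJ parameters by lambda_LJ.  There is no
soft core; window schedules must avoid the lambda_LJ = 0 end point.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import _kernels
from .constants import COULOMB_KCAL

__all__ = [
    "WaterModel",
    "IonSpec",
    "CutoffScheme",
    "CouplingState",
    "Configuration",
    "load_water_model",
    "load_ion",
    "water_water_energy",
    "ion_water_energy",
    "single_water_energy",
    "total_energy",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterModel:
    """Rigid 4-site water (TIP4P geometry).

    Site order everywhere in this package is [O, H1, H2, M].  The LJ site
    sits on O; the O charge is zero, the negative charge lives on the M
    site displaced along the bisector.
    """

    sigma_O: float
    epsilon_O: float
    q_H: float
    q_M: float
    r_OH: float
    theta_HOH: float  # degrees
    r_OM: float

    def __post_init__(self) -> None:
        net = 2 * self.q_H + self.q_M
        if abs(net) > 1e-12:
            raise ValueError(f"water model is not neutral: net charge {net}")

    @property
    def site_charges(self) -> np.ndarray:
        return np.array([0.0, self.q_H, self.q_H, self.q_M])

    @property
    def reference_sites(self) -> np.ndarray:
        """Site coordinates in the molecular frame, O at the origin.

        The HOH bisector points along +z; the molecule lies in the xz plane.
        """
        half = math.radians(self.theta_HOH) / 2
        h1 = np.array([self.r_OH * math.sin(half), 0.0, self.r_OH * math.cos(half)])
        h2 = np.array([-self.r_OH * math.sin(half), 0.0, self.r_OH * math.cos(half)])
        m = np.array([0.0, 0.0, self.r_OM])
        return np.array([np.zeros(3), h1, h2, m])


@dataclass(frozen=True)
class IonSpec:
    """A monoatomic ion: point charge plus one LJ site."""

    name: str
    charge: float  # e; +-1 for everything in scope
    sigma: float  # A
    epsilon: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("ion LJ parameters must be positive")


@dataclass(frozen=True)
class CutoffScheme:
    """Sharp molecule-based cutoffs (A): ion-O and O-O keyed."""

    r_iw: float = 11.5
    r_ww: float = 11.5

    def validate(self, box_length: float) -> None:
        half = box_length / 2
        if not (0 < self.r_ww <= half and 0 < self.r_iw <= half):
            raise ValueError(
                f"cutoffs ({self.r_iw}, {self.r_ww}) violate the minimum-image "
                f"precondition for box length {box_length}"
            )


@dataclass(frozen=True)
class CouplingState:
    """Alchemical coupling (lambda_LJ, lambda_q), each in [0, 1].

    (1, 1) is the full ion, (1, 0) the neutral LJ solute, (0, 0) the
    decoupled solute.  Scaled parameters are chi(lambda) = lambda * chi.
    """

    lambda_lj: float = 1.0
    lambda_q: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_lj < 0 or self.lambda_q < 0:
            raise ValueError("coupling parameters must be non-negative")


@dataclass
class Configuration:
    """One ion fixed at the center of a cubic box of N rigid waters.

    ``positions`` are the O sites; ``orientations`` are unit quaternions
    (w, x, y, z) rotating the molecular frame into the box frame.  All site
    coordinates are derived, and cached in ``sites`` (N, 4, 3).
    """

    box_length: float
    positions: np.ndarray  # (N, 3) O positions
    orientations: np.ndarray  # (N, 4) unit quaternions
    model: WaterModel
    sites: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box length must be positive")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 4)
        if len(self.positions) != len(self.orientations):
            raise ValueError("positions and orientations disagree on N")
        self.rebuild_sites()

    @property
    def n_waters(self) -> int:
        return len(self.positions)

    @property
    def ion_position(self) -> np.ndarray:
        return np.full(3, self.box_length / 2)

    @property
    def volume(self) -> float:
        return self.box_length ** 3

    def rebuild_sites(self) -> None:
        ref = self.model.reference_sites  # (4, 3)
        rot = _quat_to_matrix(self.orientations)  # (N, 3, 3)
        self.sites = self.positions[:, None, :] + np.einsum(
            "nij,sj->nsi", rot, ref
        )

    def update_water(self, i: int, position: np.ndarray, orientation: np.ndarray) -> None:
        w, x, y, z = orientation
        norm = math.sqrt(w * w + x * x + y * y + z * z)
        w, x, y, z = w / norm, x / norm, y / norm, z / norm
        self.positions[i] = position
        self.orientations[i] = (w, x, y, z)
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        self.sites[i] = position + self.model.reference_sites @ rot.T

    def scale_box(self, new_length: float) -> "Configuration":
        """Return a copy with molecular centers scaled; rigid geometry kept."""
        s = new_length / self.box_length
        return Configuration(
            box_length=new_length,
            positions=self.positions * s,
            orientations=self.orientations.copy(),
            model=self.model,
        )

    def copy(self) -> "Configuration":
        return Configuration(
            box_length=self.box_length,
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            model=self.model,
        )


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices for an array of unit quaternions (w, x, y, z)."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


# --------------------------------------------------------------------------
# parameter loading
# --------------------------------------------------------------------------

def _load_parameters() -> dict:
    with resources.files("ionfep.data").joinpath("parameters.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_water_model(name: str = "tip4p") -> WaterModel:
    params = _load_parameters()["water"][name]
    return WaterModel(**params)


def load_ion(name: str) -> IonSpec:
    params = _load_parameters()["ions"][name]
    return IonSpec(name=name, **params)


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------

def single_water_energy(
    config: Configuration,
    i: int,
    cutoffs: CutoffScheme,
) -> float:
    """Water-water energy of molecule ``i`` with every other molecule."""
    if config.n_waters <= 1:
        return 0.0
    model = config.model
    return float(
        _kernels.water_delta(
            config.positions,
            config.sites,
            i,
            config.box_length,
            cutoffs.r_ww ** 2,
            model.sigma_O ** 2,
            model.epsilon_O,
            model.site_charges[1:],
            COULOMB_KCAL,
        )
    )


def water_water_energy(config: Configuration, cutoffs: CutoffScheme) -> float:
    """Total water-water energy (sum over molecule pairs inside the cutoff)."""
    cutoffs.validate(config.box_length)
    if config.n_waters <= 1:
        return 0.0
    model = config.model
    return float(
        _kernels.water_total(
            config.positions,
            config.sites,
            config.box_length,
            cutoffs.r_ww ** 2,
            model.sigma_O ** 2,
            model.epsilon_O,
            model.site_charges[1:],
            COULOMB_KCAL,
        )
    )


def _scaled_lj(ion: IonSpec, model: WaterModel, lambda_lj: float) -> tuple[float, float]:
    """Geometric-mean combination of the lambda-scaled ion LJ parameters."""
    sigma2 = lambda_lj * ion.sigma * model.sigma_O
    epsilon = math.sqrt(lambda_lj * ion.epsilon * model.epsilon_O)
    return sigma2, epsilon


def ion_water_energy(
    config: Configuration,
    ion: IonSpec,
    coupling: CouplingState,
    cutoffs: CutoffScheme,
    *,
    subset: np.ndarray | None = None,
) -> float:
    """Ion-water energy under the given alchemical coupling.

    LJ parameters are combined geometrically from the lambda-scaled ion
    parameters and the water O parameters; the Coulomb part is exactly
    linear in lambda_q.  ``subset`` restricts the sum to selected waters
    (used for incremental moves).
    """
    cutoffs.validate(config.box_length)
    if config.n_waters == 0:
        return 0.0
    model = config.model
    sigma2, epsilon = _scaled_lj(ion, model, coupling.lambda_lj)
    cx, cy, cz = config.ion_position
    args = (
        config.box_length,
        cutoffs.r_iw ** 2,
        sigma2,
        epsilon,
        coupling.lambda_q * ion.charge,
        model.site_charges[1:],
        COULOMB_KCAL,
        coupling.lambda_lj > 0,
        coupling.lambda_q != 0,
    )
    if subset is None:
        return float(
            _kernels.ion_water(config.positions, config.sites, cx, cy, cz, *args)
        )
    return float(
        sum(
            _kernels.ion_water_single(
                config.positions, config.sites, int(j), cx, cy, cz, *args
            )
            for j in np.atleast_1d(subset)
        )
    )


def total_energy(
    config: Configuration,
    ion: IonSpec,
    coupling: CouplingState,
    cutoffs: CutoffScheme,
) -> float:
    """Full potential energy: all water pairs plus the ion-water term."""
    return water_water_energy(config, cutoffs) + ion_water_energy(
        config, ion, coupling, cutoffs
    )
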