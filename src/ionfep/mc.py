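"""Metropolis Monte Carlo in the NPT ensemble for the fixed-ion + water system.

Moves are (a) combined random translation + rotation of one randomly chosen
water (the ion never moves) and (b) volume changes sampled linearly in V,
with molecular centers rescaled and rigid geometry preserved.  The NPT
acceptance weight for a volume move V -> V' is

    min(1, exp(-beta [dU + P dV] + N ln(V'/V)))

with N the number of waters; for an ideal (non-interacting) system this
distribution gives <V> = (N+1) kT / P, which the test suite uses as an
analytic oracle.

The total potential energy is tracked incrementally and checked against a
from-scratch recomputation at a configurable interval; drift beyond
tolerance aborts the run, because a silently corrupted energy ledger would
poison every free-energy estimate downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ATM_A3_TO_KCAL, BOLTZMANN_KCAL
from .forcefield import (
    Configuration,
    CouplingState,
    CutoffScheme,
    IonSpec,
    ion_water_energy,
    single_water_energy,
    water_water_energy,
)

__all__ = ["ThermoState", "MoveSettings", "RunStats", "NptMonteCarlo"]


@dataclass(frozen=True)
class ThermoState:
    """Temperature (K) and pressure (atm)."""

    T: float = 298.15
    P: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.P <= 0:
            raise ValueError("T and P must be positive")

    @property
    def beta(self) -> float:
        """1/kT in mol/kcal."""
        return 1.0 / (BOLTZMANN_KCAL * self.T)


@dataclass
class MoveSettings:
    max_translation: float = 0.15  # A
    max_rotation: float = 0.15  # rad
    max_volume: float = 150.0  # A^3
    p_volume: float = 0.02  # probability of attempting a volume move
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_translation, self.max_rotation, self.max_volume) <= 0:
            raise ValueError("move amplitudes must be positive")
        if not 0 <= self.p_volume <= 1:
            raise ValueError("move-type probabilities must lie in [0, 1]")


@dataclass
class RunStats:
    attempted: dict = field(default_factory=lambda: {"particle": 0, "volume": 0})
    accepted: dict = field(default_factory=lambda: {"particle": 0, "volume": 0})
    energy_trace: list = field(default_factory=list)
    volume_trace: list = field(default_factory=list)

    def acceptance(self, kind: str) -> float:
        att = self.attempted[kind]
        return self.accepted[kind] / att if att else 0.0


class EnergyDriftError(RuntimeError):
    """Incremental energy bookkeeping diverged from full recomputation."""


class NptMonteCarlo:
    """Metropolis NPT sampler.

    Parameters
    ----------
    config : starting configuration (ion implicitly at the box center).
    thermo, settings : state point and move parameters.
    ion, coupling, cutoffs : interaction model; ``interacting=False`` turns
        every energy evaluation into zero (the ideal-gas reference used in
        the analytic volume check).
    """

    def __init__(
        self,
        config: Configuration,
        thermo: ThermoState,
        settings: MoveSettings,
        ion: IonSpec | None = None,
        coupling: CouplingState | None = None,
        cutoffs: CutoffScheme | None = None,
        *,
        interacting: bool = True,
        check_interval: int = 20000,
        drift_tolerance: float = 1e-6,
    ) -> None:
        self.config = config.copy()
        self.thermo = thermo
        self.settings = settings
        self.ion = ion
        self.coupling = coupling if coupling is not None else CouplingState()
        self.cutoffs = cutoffs if cutoffs is not None else CutoffScheme()
        self.interacting = interacting and ion is not None
        self.check_interval = check_interval
        self.drift_tolerance = drift_tolerance
        self.rng = np.random.default_rng(settings.seed)
        self.stats = RunStats()
        self.energy = self._full_energy(self.config)
        self.trials = 0

    # -- energies -----------------------------------------------------------

    def _full_energy(self, config: Configuration) -> float:
        if not self.interacting:
            return 0.0
        return water_water_energy(config, self.cutoffs) + ion_water_energy(
            config, self.ion, self.coupling, self.cutoffs
        )

    def _water_energy(self, i: int) -> float:
        if not self.interacting:
            return 0.0
        return single_water_energy(self.config, i, self.cutoffs) + ion_water_energy(
            self.config, self.ion, self.coupling, self.cutoffs, subset=np.array([i])
        )

    # -- moves --------------------------------------------------------------

    def _metropolis(self, log_weight: float) -> bool:
        if log_weight >= 0:
            return True
        return self.rng.random() < math.exp(log_weight)

    def attempt_particle_move(self) -> bool:
        """Translate + rotate one random water; ion never selected."""
        n = self.config.n_waters
        if n == 0:
            return False
        i = int(self.rng.integers(n))
        old_pos = self.config.positions[i].copy()
        old_quat = self.config.orientations[i].copy()
        old_sites = self.config.sites[i].copy()
        e_old = self._water_energy(i)

        disp = self.rng.uniform(-1, 1, 3) * self.settings.max_translation
        new_pos = (old_pos + disp) % self.config.box_length
        axis = self.rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = self.rng.uniform(-1, 1) * self.settings.max_rotation
        dq = np.concatenate([[math.cos(angle / 2)], math.sin(angle / 2) * axis])
        new_quat = _quat_multiply(dq, old_quat)

        self.config.update_water(i, new_pos, new_quat)
        e_new = self._water_energy(i)
        du = e_new - e_old
        self.stats.attempted["particle"] += 1
        if self._metropolis(-self.thermo.beta * du):
            self.energy += du
            self.stats.accepted["particle"] += 1
            return True
        # restore the prior state bit-for-bit
        self.config.positions[i] = old_pos
        self.config.orientations[i] = old_quat
        self.config.sites[i] = old_sites
        return False

    def attempt_volume_move(self) -> bool:
        """Volume change uniform in V; centers rescaled, ion stays central."""
        v_old = self.config.volume
        v_new = v_old + self.rng.uniform(-1, 1) * self.settings.max_volume
        self.stats.attempted["volume"] += 1
        if v_new <= 0:
            return False
        new_length = v_new ** (1.0 / 3.0)
        if self.interacting and new_length < 2 * max(self.cutoffs.r_iw, self.cutoffs.r_ww):
            # shrinking below twice the cutoff would break minimum imaging
            return False
        new_config = self.config.scale_box(new_length)
        e_new = self._full_energy(new_config)
        du = e_new - self.energy
        n = self.config.n_waters
        pdv = self.thermo.P * (v_new - v_old) * ATM_A3_TO_KCAL
        log_w = -self.thermo.beta * (du + pdv) + n * math.log(v_new / v_old)
        if self._metropolis(log_w):
            self.config = new_config
            self.energy = e_new
            self.stats.accepted["volume"] += 1
            return True
        return False

    # -- driver -------------------------------------------------------------

    def step(self) -> bool:
        self.trials += 1
        if self.rng.random() < self.settings.p_volume:
            accepted = self.attempt_volume_move()
        else:
            accepted = self.attempt_particle_move()
        if self.check_interval and self.trials % self.check_interval == 0:
            self.verify_energy()
        return accepted

    def run(
        self,
        n_trials: int,
        *,
        observer=None,
        stride: int = 100,
    ) -> RunStats:
        """Run ``n_trials`` Metropolis trials.

        ``observer(engine)`` is called every ``stride`` trials (after the
        trial); FEP drivers use it to collect perturbation energies.
        Identical seed + configuration + settings give identical
        trajectories.
        """
        for _ in range(n_trials):
            self.step()
            if self.trials % stride == 0:
                self.stats.energy_trace.append(self.energy)
                self.stats.volume_trace.append(self.config.volume)
                if observer is not None:
                    observer(self)
        return self.stats

    def equilibrate(self, n_trials: int, *, target_acceptance: float = 0.4,
                    tune_interval: int = 1000) -> None:
        """Equilibration with amplitude auto-tuning, frozen afterwards."""
        window_att = window_acc = 0
        for _ in range(n_trials):
            before = self.stats.accepted["particle"]
            att_before = self.stats.attempted["particle"]
            self.step()
            window_acc += self.stats.accepted["particle"] - before
            window_att += self.stats.attempted["particle"] - att_before
            if window_att >= tune_interval:
                rate = window_acc / window_att
                factor = 1.1 if rate > target_acceptance else 1 / 1.1
                self.settings.max_translation = min(
                    self.settings.max_translation * factor, self.config.box_length / 4
                )
                self.settings.max_rotation = min(
                    self.settings.max_rotation * factor, math.pi
                )
                window_att = window_acc = 0

    def verify_energy(self) -> float:
        """Compare the incremental ledger against a from-scratch total."""
        fresh = self._full_energy(self.config)
        drift = abs(fresh - self.energy)
        if drift > self.drift_tolerance:
            raise EnergyDriftError(
                f"energy bookkeeping drift {drift:.3e} kcal/mol after "
                f"{self.trials} trials"
            )
        self.energy = fresh
        return drift


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )
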