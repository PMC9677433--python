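"""Truncated pair energies against independently coded site-site oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionfep import (
    Configuration,
    CouplingState,
    CutoffScheme,
    ion_water_energy,
    load_ion,
    water_water_energy,
)
from ionfep.constants import COULOMB_KCAL
from ionfep.forcefield import single_water_energy
from ionfep.synthetic import generate_water_box, random_quaternions

# ---------------------------------------------------------------------------
# brute-force oracles, written without reference to the package internals
# ---------------------------------------------------------------------------


def oracle_water_pair(config, i, j, r_ww):
    """All-site double loop for one water pair, molecule-based min image."""
    m = config.model
    L = config.box_length
    d = config.positions[j] - config.positions[i]
    shift = L * np.round(d / L)
    if np.linalg.norm(d - shift) >= r_ww:
        return 0.0
    r2 = float((d - shift) @ (d - shift))
    s6 = (m.sigma_O**2 / r2) ** 3
    e = 4 * m.epsilon_O * (s6 * s6 - s6)
    q = m.site_charges
    for a in range(4):
        for b in range(4):
            if q[a] == 0.0 or q[b] == 0.0:
                continue
            r = np.linalg.norm((config.sites[j, b] - shift) - config.sites[i, a])
            e += COULOMB_KCAL * q[a] * q[b] / r
    return e


def oracle_ion_water(config, ion, coupling, r_iw):
    m = config.model
    L = config.box_length
    center = config.ion_position
    e = 0.0
    sigma = math.sqrt(coupling.lambda_lj * ion.sigma * m.sigma_O)
    epsilon = math.sqrt(coupling.lambda_lj * ion.epsilon * m.epsilon_O)
    for j in range(config.n_waters):
        d = config.positions[j] - center
        shift = L * np.round(d / L)
        r = np.linalg.norm(d - shift)
        if r >= r_iw:
            continue
        if coupling.lambda_lj > 0:
            s6 = (sigma / r) ** 6
            e += 4 * epsilon * (s6 * s6 - s6)
        for b in range(1, 4):
            rb = np.linalg.norm((config.sites[j, b] - shift) - center)
            e += (
                COULOMB_KCAL
                * coupling.lambda_q
                * ion.charge
                * m.site_charges[b]
                / rb
            )
    return e


def make_two_water_config(model, separation, orient=(0.3, 0.5, -0.2, 0.8)):
    quats = np.array([[1.0, 0, 0, 0], list(orient)])
    quats[1] /= np.linalg.norm(quats[1])
    pos = np.array([[25.0, 25.0, 25.0], [25.0, 25.0, 25.0 + separation]])
    return Configuration(box_length=50.0, positions=pos, orientations=quats, model=model)


# ---------------------------------------------------------------------------
# water-water
# ---------------------------------------------------------------------------


def test_pair_beyond_cutoff_contributes_nothing(water_model):
    cfg = make_two_water_config(water_model, separation=12.0)
    assert water_water_energy(cfg, CutoffScheme(11.5, 11.5)) == 0.0


def test_single_water_has_no_pairs(water_model):
    cfg = Configuration(
        box_length=20.0,
        positions=np.array([[10.0, 10.0, 10.0]]),
        orientations=np.array([[1.0, 0, 0, 0]]),
        model=water_model,
    )
    assert water_water_energy(cfg, CutoffScheme(9.0, 9.0)) == 0.0


@pytest.mark.parametrize("separation", [2.8, 3.5, 5.0, 11.4])
def test_water_pair_matches_site_site_oracle(water_model, separation):
    cfg = make_two_water_config(water_model, separation)
    expected = oracle_water_pair(cfg, 0, 1, 11.5)
    assert water_water_energy(cfg, CutoffScheme(11.5, 11.5)) == pytest.approx(
        expected, abs=1e-10
    )


def test_box_total_matches_oracle_pair_sum(small_box, small_cutoffs):
    expected = sum(
        oracle_water_pair(small_box, i, j, small_cutoffs.r_ww)
        for i in range(small_box.n_waters)
        for j in range(i + 1, small_box.n_waters)
    )
    assert water_water_energy(small_box, small_cutoffs) == pytest.approx(
        expected, abs=1e-8
    )


def test_truncation_is_all_or_nothing_per_molecule_pair(water_model):
    # O-O just outside the cutoff: zero even though H sites are closer
    cfg = make_two_water_config(water_model, separation=8.001)
    assert water_water_energy(cfg, CutoffScheme(8.0, 8.0)) == 0.0
    cfg = make_two_water_config(water_model, separation=7.999)
    assert water_water_energy(cfg, CutoffScheme(8.0, 8.0)) != 0.0


def test_relabeling_invariance(small_box, small_cutoffs):
    rng = np.random.default_rng(0)
    perm = rng.permutation(small_box.n_waters)
    shuffled = Configuration(
        box_length=small_box.box_length,
        positions=small_box.positions[perm],
        orientations=small_box.orientations[perm],
        model=small_box.model,
    )
    assert water_water_energy(shuffled, small_cutoffs) == pytest.approx(
        water_water_energy(small_box, small_cutoffs), abs=1e-8
    )


@given(
    shift=st.tuples(
        st.floats(-30, 30, allow_nan=False),
        st.floats(-30, 30, allow_nan=False),
        st.floats(-30, 30, allow_nan=False),
    )
)
def test_translation_invariance_under_pbc(shift):
    # the ion sits at the box center, so only the water-water term is
    # translation invariant under a rigid shift of all molecules
    box = generate_water_box(12, seed=7)
    cutoffs = CutoffScheme(0.45 * box.box_length, 0.45 * box.box_length)
    base_ww = water_water_energy(box, cutoffs)
    moved = Configuration(
        box_length=box.box_length,
        positions=(box.positions + np.array(shift)) % box.box_length,
        orientations=box.orientations,
        model=box.model,
    )
    assert water_water_energy(moved, cutoffs) == pytest.approx(base_ww, abs=1e-7)


def test_cutoff_beyond_half_box_rejected(small_box):
    bad = CutoffScheme(r_iw=small_box.box_length, r_ww=3.0)
    with pytest.raises(ValueError, match="minimum-image"):
        water_water_energy(small_box, bad)


# ---------------------------------------------------------------------------
# ion-water
# ---------------------------------------------------------------------------


def test_fully_decoupled_ion_has_zero_energy(small_box, small_cutoffs, potassium):
    assert (
        ion_water_energy(
            small_box, potassium, CouplingState(0.0, 0.0), small_cutoffs
        )
        == 0.0
    )


def test_coulomb_part_linear_in_lambda_q(small_box, small_cutoffs, potassium):
    lj_only = ion_water_energy(
        small_box, potassium, CouplingState(1.0, 0.0), small_cutoffs
    )
    full = ion_water_energy(small_box, potassium, CouplingState(1.0, 1.0), small_cutoffs)
    half = ion_water_energy(small_box, potassium, CouplingState(1.0, 0.5), small_cutoffs)
    assert half - lj_only == pytest.approx((full - lj_only) / 2, rel=1e-12)


def test_lj_part_vanishes_at_lambda_zero(small_box, small_cutoffs, potassium):
    coul_only = ion_water_energy(
        small_box, potassium, CouplingState(0.0, 1.0), small_cutoffs
    )
    full_coul = ion_water_energy(
        small_box, potassium, CouplingState(1.0, 1.0), small_cutoffs
    ) - ion_water_energy(small_box, potassium, CouplingState(1.0, 0.0), small_cutoffs)
    assert coul_only == pytest.approx(full_coul, rel=1e-12)


@pytest.mark.parametrize("ion_name", ["K", "Br"])
@pytest.mark.parametrize("lam", [(1.0, 1.0), (0.6, 0.3), (1.0, 0.0)])
def test_ion_water_matches_explicit_site_oracle(small_box, small_cutoffs, ion_name, lam):
    ion = load_ion(ion_name)
    coupling = CouplingState(*lam)
    expected = oracle_ion_water(small_box, ion, coupling, small_cutoffs.r_iw)
    assert ion_water_energy(small_box, ion, coupling, small_cutoffs) == pytest.approx(
        expected, abs=1e-9
    )


def test_negative_coupling_rejected():
    with pytest.raises(ValueError):
        CouplingState(-0.1, 0.5)
    with pytest.raises(ValueError):
        CouplingState(0.5, -0.1)


def test_incremental_deltas_match_full_recomputation(small_box, small_cutoffs):
    """Sum of single-molecule deltas over a move sequence equals the change
    in the full pair sum."""
    rng = np.random.default_rng(3)
    cfg = small_box
    total_before = water_water_energy(cfg, small_cutoffs)
    delta_sum = 0.0
    for _ in range(40):
        i = int(rng.integers(cfg.n_waters))
        e_old = single_water_energy(cfg, i, small_cutoffs)
        new_pos = (cfg.positions[i] + rng.uniform(-0.3, 0.3, 3)) % cfg.box_length
        cfg.update_water(i, new_pos, random_quaternions(1, rng)[0])
        delta_sum += single_water_energy(cfg, i, small_cutoffs) - e_old
    total_after = water_water_energy(cfg, small_cutoffs)
    assert total_after - total_before == pytest.approx(delta_sum, abs=1e-8)
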