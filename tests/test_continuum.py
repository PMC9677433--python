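"""Continuum corrections: Born closed forms, the apparent-surface-charge
solver, and the truncation corrections C_LR, C_WW, C_BA."""

import numpy as np
import pytest

from ionfep import (
    CorrectionLedger,
    DielectricMedium,
    born_energy,
    build_T,
    c_ba,
    c_lr,
    c_ww,
    c_ww_discrete,
    charging_free_energy,
    dg_q,
    solve_charges,
    tessellate_sphere,
)
from ionfep.constants import COULOMB_KCAL


# ---------------------------------------------------------------------------
# Born closed form and C_LR
# ---------------------------------------------------------------------------


def test_vacuum_gives_zero():
    assert born_energy(1.0, 13.2, DielectricMedium(1.0)) == 0.0


def test_born_at_water_dielectric(medium_1atm):
    assert born_energy(1.0, 13.2, medium_1atm) == pytest.approx(-12.42, abs=0.005)


def test_conductor_limit():
    huge = DielectricMedium(1e12)
    assert born_energy(1.0, 13.2, huge) == pytest.approx(
        -COULOMB_KCAL / (2 * 13.2), rel=1e-9
    )
    assert born_energy(1.0, 13.2, huge) == pytest.approx(-12.58, abs=0.005)


def test_born_scales_as_charge_squared(medium_1atm):
    assert born_energy(0.5, 10.0, medium_1atm) == pytest.approx(
        born_energy(1.0, 10.0, medium_1atm) / 4, rel=1e-12
    )
    assert born_energy(-1.0, 10.0, medium_1atm) == born_energy(1.0, 10.0, medium_1atm)


def test_invalid_inputs_rejected(medium_1atm):
    with pytest.raises(ValueError):
        born_energy(1.0, -1.0, medium_1atm)
    with pytest.raises(ValueError):
        DielectricMedium(0.5)


def test_c_lr_with_zero_delta_is_born_at_cutoff(medium_1atm):
    assert c_lr(1.0, 11.5, medium_1atm, delta=0.0) == born_energy(
        1.0, 11.5, medium_1atm
    )


def test_c_lr_default_water_shell(medium_1atm):
    # default delta places the dielectric boundary one water beyond the cutoff
    assert c_lr(1.0, 11.5, medium_1atm) == pytest.approx(-12.42, abs=0.005)


def test_c_lr_halves_when_radius_doubles(medium_1atm):
    assert c_lr(1.0, 11.5, medium_1atm, delta=1.7) == pytest.approx(
        2 * c_lr(1.0, 24.7, medium_1atm, delta=1.7), rel=1e-12
    )


# ---------------------------------------------------------------------------
# tessellation and solver
# ---------------------------------------------------------------------------


def test_tessellation_invariants():
    cav = tessellate_sphere(500, 13.2)
    assert np.allclose(np.linalg.norm(cav.points, axis=1), 13.2, atol=1e-10)
    assert np.sum(cav.areas) == pytest.approx(4 * np.pi * 13.2**2, rel=1e-9)
    again = tessellate_sphere(500, 13.2)
    assert np.array_equal(cav.points, again.points)
    with pytest.raises(ValueError):
        tessellate_sphere(1, 13.2)


def test_quasi_uniform_spacing():
    cav = tessellate_sphere(400, 10.0)
    d = np.linalg.norm(cav.points[:, None] - cav.points[None], axis=-1)
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    assert nearest.max() / nearest.min() < 2.0


def test_t_matrix_cutoff_mask_symmetric_diagonal_untouched(medium_1atm):
    cav = tessellate_sphere(200, 13.2)
    tm = build_T(cav, medium_1atm, cutoff=11.5)
    assert tm.mask is not None
    assert np.array_equal(tm.mask, tm.mask.T)
    assert not tm.mask.diagonal().any()
    assert np.all(tm.T.diagonal() != 0)
    with pytest.raises(ValueError):
        build_T(cav, medium_1atm, cutoff=-1.0)


def test_zero_charge_induces_no_polarization(medium_1atm):
    tm = build_T(tessellate_sphere(100, 13.2), medium_1atm)
    charges = solve_charges(tm, 0.0)
    assert np.all(charges.charges == 0.0)
    assert dg_q(charges, 0.0) == 0.0


def test_gauss_law_total_charge(medium_1atm):
    tm = build_T(tessellate_sphere(1000, 13.2), medium_1atm)
    total = solve_charges(tm, 1.0).total
    expected = -(1 - 1 / medium_1atm.eps_r)
    assert total == pytest.approx(expected, rel=0.01)


def test_central_charge_polarization_is_uniform(medium_1atm):
    q = solve_charges(build_T(tessellate_sphere(500, 13.2), medium_1atm), 1.0).charges
    assert np.std(q) / abs(np.mean(q)) < 0.02


def test_dg_q_converges_to_born_monotonically(medium_1atm):
    born = born_energy(1.0, 13.2, medium_1atm)
    errors = [
        abs(charging_free_energy(1.0, 13.2, medium_1atm, n, closure="disk") - born)
        for n in (100, 250, 500, 1000)
    ]
    assert all(a > b for a, b in zip(errors, errors[1:]))
    assert errors[-1] / abs(born) < 0.005


# ---------------------------------------------------------------------------
# C_WW
# ---------------------------------------------------------------------------


def test_cutoff_covering_whole_cavity_gives_zero(medium_1atm):
    assert c_ww(10.0, medium_1atm, 20.5, n=200) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "r_lr,cut,published",
    [(13.2, 11.5, 5.03), (10.0, 10.0, 5.63), (10.0, 11.5, 4.55), (11.5, 10.0, 5.79)],
)
def test_c_ww_reproduces_published_table(medium_1atm, r_lr, cut, published):
    assert c_ww(r_lr, medium_1atm, cut) == pytest.approx(published, abs=0.1)


def test_c_ww_positive_and_nonincreasing_in_cutoff(medium_1atm):
    values = [c_ww(13.2, medium_1atm, cut, n=400) for cut in (10.0, 11.5, 14.0, 20.0)]
    assert values[0] > 0
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_c_ww_scales_as_charge_squared(medium_1atm):
    full = c_ww(13.2, medium_1atm, 11.5, n=200, q=1.0)
    half = c_ww(13.2, medium_1atm, 11.5, n=200, q=0.5)
    assert half == pytest.approx(full / 4, rel=1e-9)


def test_c_ww_between_literature_bracket(medium_1atm):
    # independent corrections reported for comparable cutoffs: 3.3 (12 A)
    # and 7.32 (11 A) kcal/mol
    val = c_ww(13.2, medium_1atm, 11.5)
    assert 3.3 < val < 7.32


def test_discrete_charging_sum_matches_continuous(medium_1atm):
    total, partial = c_ww_discrete(1.0, 0.05, 10, 13.2, medium_1atm, 11.5)
    assert total == pytest.approx(c_ww(13.2, medium_1atm, 11.5), abs=0.01)
    assert len(partial) == 20
    assert np.all(np.diff(partial) > 0)  # each charging step adds error
    # partial sum at half charge shows the quadratic scaling
    assert partial[9] == pytest.approx(total / 4, rel=1e-9)


def test_discrete_charging_zero_charge(medium_1atm):
    total, partial = c_ww_discrete(0.0, 0.05, 10, 13.2, medium_1atm, 11.5, n=100)
    assert total == 0.0
    assert np.all(partial == 0.0)


def test_corrections_sum_nearly_pressure_independent():
    # experimental dielectric constants at 1 and 8000 atm
    lo = DielectricMedium(78.4)
    hi = DielectricMedium(98.5)
    sum_lo = c_lr(1.0, 11.5, lo) + c_ww(13.2, lo, 11.5)
    sum_hi = c_lr(1.0, 11.5, hi) + c_ww(13.2, hi, 11.5)
    assert abs(sum_lo - sum_hi) < 0.01


# ---------------------------------------------------------------------------
# C_BA and the correction ledger
# ---------------------------------------------------------------------------


def test_c_ba_boundary_condition_at_1atm():
    assert c_ba(-7.8, 0.03303, 0.03303) == pytest.approx(7.8, rel=1e-12)


def test_c_ba_proportional_to_density():
    base = c_ba(-7.8, 0.03303, 0.03303)
    assert c_ba(-7.8, 2 * 0.03303, 0.03303) == pytest.approx(2 * base, rel=1e-12)
    assert c_ba(0.0, 0.05, 0.03303) == 0.0


def test_ledger_identities_hold_exactly():
    led = CorrectionLedger(c_lr=-12.42, c_ww=5.03, c_ba=7.8, aq=-13.2)
    assert led.c1 == -12.42 + 5.03
    assert led.c2 == led.c1 + 7.8
    assert led.c3 == led.c1 - (-13.2)
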