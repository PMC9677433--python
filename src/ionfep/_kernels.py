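"""Numba-compiled inner loops for the truncated pair energies.

These kernels are an implementation detail of :mod:`ionfep.forcefield`;
they carry the same molecule-based sharp-truncation semantics (O-O keyed
for water-water, ion-O keyed for ion-water, whole-molecule image shifts).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _pair_ww(pos, sites, i, j, L, rww2, sig2, eps, qc, kc):
    dx = pos[j, 0] - pos[i, 0]
    dy = pos[j, 1] - pos[i, 1]
    dz = pos[j, 2] - pos[i, 2]
    sx = L * round(dx / L)
    sy = L * round(dy / L)
    sz = L * round(dz / L)
    mx = dx - sx
    my = dy - sy
    mz = dz - sz
    r2 = mx * mx + my * my + mz * mz
    if r2 >= rww2:
        return 0.0
    s6 = (sig2 / r2) ** 3
    e = 4.0 * eps * (s6 * s6 - s6)
    for a in range(1, 4):
        ax = sites[i, a, 0]
        ay = sites[i, a, 1]
        az = sites[i, a, 2]
        for b in range(1, 4):
            bx = sites[j, b, 0] - sx - ax
            by = sites[j, b, 1] - sy - ay
            bz = sites[j, b, 2] - sz - az
            e += kc * qc[a - 1] * qc[b - 1] / np.sqrt(bx * bx + by * by + bz * bz)
    return e


@njit(cache=True)
def water_delta(pos, sites, i, L, rww2, sig2, eps, qc, kc):
    """Energy of molecule i with every other molecule."""
    e = 0.0
    for j in range(pos.shape[0]):
        if j != i:
            e += _pair_ww(pos, sites, i, j, L, rww2, sig2, eps, qc, kc)
    return e


@njit(cache=True)
def water_total(pos, sites, L, rww2, sig2, eps, qc, kc):
    """Sum over distinct molecule pairs."""
    e = 0.0
    n = pos.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            e += _pair_ww(pos, sites, i, j, L, rww2, sig2, eps, qc, kc)
    return e


@njit(cache=True)
def ion_water(pos, sites, cx, cy, cz, L, riw2, sig2, eps, qion, qc, kc, lj_on, coul_on):
    """Ion at (cx, cy, cz) against all waters; sharp ion-O truncation.

    ``sig2``/``eps`` are the lambda-scaled combined LJ parameters; ``qion``
    is the lambda-scaled ion charge.
    """
    e = 0.0
    for j in range(pos.shape[0]):
        dx = pos[j, 0] - cx
        dy = pos[j, 1] - cy
        dz = pos[j, 2] - cz
        sx = L * round(dx / L)
        sy = L * round(dy / L)
        sz = L * round(dz / L)
        mx = dx - sx
        my = dy - sy
        mz = dz - sz
        r2 = mx * mx + my * my + mz * mz
        if r2 >= riw2:
            continue
        if lj_on:
            s6 = (sig2 / r2) ** 3
            e += 4.0 * eps * (s6 * s6 - s6)
        if coul_on:
            for b in range(1, 4):
                bx = sites[j, b, 0] - sx - cx
                by = sites[j, b, 1] - sy - cy
                bz = sites[j, b, 2] - sz - cz
                e += kc * qion * qc[b - 1] / np.sqrt(bx * bx + by * by + bz * bz)
    return e


@njit(cache=True)
def ion_water_single(pos, sites, j, cx, cy, cz, L, riw2, sig2, eps, qion, qc, kc,
                     lj_on, coul_on):
    dx = pos[j, 0] - cx
    dy = pos[j, 1] - cy
    dz = pos[j, 2] - cz
    sx = L * round(dx / L)
    sy = L * round(dy / L)
    sz = L * round(dz / L)
    mx = dx - sx
    my = dy - sy
    mz = dz - sz
    r2 = mx * mx + my * my + mz * mz
    e = 0.0
    if r2 >= riw2:
        return e
    if lj_on:
        s6 = (sig2 / r2) ** 3
        e += 4.0 * eps * (s6 * s6 - s6)
    if coul_on:
        for b in range(1, 4):
            bx = sites[j, b, 0] - sx - cx
            by = sites[j, b, 1] - sy - cy
            bz = sites[j, b, 2] - sz - cz
            e += kc * qion * qc[b - 1] / np.sqrt(bx * bx + by * by + bz * bz)
    return e
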