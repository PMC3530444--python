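"""Compiled inner loops of the Metropolis dynamics.

The kernels operate on the dense geometry arrays (volumes, perimeters,
interface matrix) and mirror, op for op, the reference implementations in
:mod:`gonadcpm.energy`; the test suite checks the two against each other.

The label image is handed in with a one-pixel medium frame (the
fixed-medium boundary condition), so neighbour reads need no bounds
checks; flips are only ever proposed at interior pixels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEDIUM = 0


@njit(cache=True, inline="always")
def _delta_u(padded, kinds, volumes, perims, K3, V03, C3, E33, r, c, a, b):
    """Energy change of flipping padded[r, c] from a to b, from the local
    4-neighbourhood only."""
    ka = kinds[a]
    kb = kinds[b]
    dla = 0
    dlb = 0
    du = 0.0
    for k in range(4):
        if k == 0:
            ln = padded[r - 1, c]
        elif k == 1:
            ln = padded[r + 1, c]
        elif k == 2:
            ln = padded[r, c - 1]
        else:
            ln = padded[r, c + 1]
        if ln == a:
            du += E33[ka, kb]
            dla += 1
            dlb += 1
        elif ln == b:
            du -= E33[ka, kb]
            dla -= 1
            dlb -= 1
        else:
            kn = kinds[ln]
            du += E33[kb, kn] - E33[ka, kn]
            dla -= 1
            dlb += 1
    if ka != MEDIUM:
        du += K3[ka] * (0.5 - (volumes[a] - V03[ka]))
        la = float(perims[a])
        du += 0.5 * C3[ka] * ((la + dla) ** 2 - la * la)
    if kb != MEDIUM:
        du += K3[kb] * ((volumes[b] - V03[kb]) + 0.5)
        lb = float(perims[b])
        du += 0.5 * C3[kb] * ((lb + dlb) ** 2 - lb * lb)
    return du


@njit(cache=True, inline="always")
def _apply_flip(padded, volumes, perims, iface, r, c, a, b):
    for k in range(4):
        if k == 0:
            ln = padded[r - 1, c]
        elif k == 1:
            ln = padded[r + 1, c]
        elif k == 2:
            ln = padded[r, c - 1]
        else:
            ln = padded[r, c + 1]
        if ln == a:
            iface[a, b] += 1
            iface[b, a] += 1
            perims[a] += 1
            perims[b] += 1
        elif ln == b:
            iface[a, b] -= 1
            iface[b, a] -= 1
            perims[a] -= 1
            perims[b] -= 1
        else:
            iface[a, ln] -= 1
            iface[ln, a] -= 1
            iface[b, ln] += 1
            iface[ln, b] += 1
            perims[a] -= 1
            perims[b] += 1
    volumes[a] -= 1
    volumes[b] += 1
    padded[r, c] = b


@njit(cache=True)
def run_mcs(
    padded,
    kinds,
    volumes,
    perims,
    iface,
    K3,
    V03,
    C3,
    E33,
    beta,
    n_mcs,
    rng,
    conn8,
):
    """Run ``n_mcs`` Monte Carlo steps in place; return accepted-flip count.

    One MCS is height*width flip attempts. Each attempt draws boundary
    pixels uniformly (rejection sampling over the lattice), proposes the
    label of a uniformly chosen differing neighbour (4- or, with ``conn8``,
    8-connected for the proposal pool only) and applies the Metropolis
    rule. Returns -1 if the lattice has no boundary pixel at all.
    """
    h = padded.shape[0] - 2
    w = padded.shape[1] - 2
    n_attempts = h * w
    max_tries = 64 * n_attempts
    accepted = 0
    cand = np.empty(8, np.int32)
    for _ in range(n_mcs):
        for _attempt in range(n_attempts):
            nd = 0
            a = MEDIUM
            r = 0
            c = 0
            for _t in range(max_tries):
                r = 1 + int(rng.random() * h)
                c = 1 + int(rng.random() * w)
                a = padded[r, c]
                nd = 0
                ln = padded[r - 1, c]
                if ln != a:
                    cand[nd] = ln
                    nd += 1
                ln = padded[r + 1, c]
                if ln != a:
                    cand[nd] = ln
                    nd += 1
                ln = padded[r, c - 1]
                if ln != a:
                    cand[nd] = ln
                    nd += 1
                ln = padded[r, c + 1]
                if ln != a:
                    cand[nd] = ln
                    nd += 1
                if conn8:
                    ln = padded[r - 1, c - 1]
                    if ln != a:
                        cand[nd] = ln
                        nd += 1
                    ln = padded[r - 1, c + 1]
                    if ln != a:
                        cand[nd] = ln
                        nd += 1
                    ln = padded[r + 1, c - 1]
                    if ln != a:
                        cand[nd] = ln
                        nd += 1
                    ln = padded[r + 1, c + 1]
                    if ln != a:
                        cand[nd] = ln
                        nd += 1
                if nd > 0:
                    break
            if nd == 0:
                return -1  # single-label lattice: no boundary anywhere
            b = cand[int(rng.random() * nd)]
            du = _delta_u(padded, kinds, volumes, perims, K3, V03, C3, E33, r, c, a, b)
            if du <= 0.0 or rng.random() < np.exp(-beta * du):
                _apply_flip(padded, volumes, perims, iface, r, c, a, b)
                accepted += 1
    return accepted
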