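"""Independent brute-force oracles used only by the tests.

Everything here is written against the raw physics, not against the package
under test: a vectorized bisection on the charge balance, and exhaustive
grid searches for the least-squares pKa estimators.
"""

from __future__ import annotations

import numpy as np


def oracle_ph(pka, c_acid, v0, c_base, v_added, pkw=13.997, n_iter=120):
    """pH by plain bisection on log10[H+] over [1e-14, 1] M.

    All arguments broadcast; returns an array of pH values.  The charge
    balance is assembled independently of the package:
    Na+ + H+ - A- - OH- = 0 with dilution by (v0 + v).
    """
    pka, c_acid, v0, c_base, v_added = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (pka, c_acid, v0, c_base, v_added))
    )
    ka = 10.0 ** (-pka)
    kw = 10.0 ** (-pkw)
    vtot = v0 + v_added
    ca = c_acid * v0 / vtot
    na = c_base * v_added / vtot

    def balance(x):
        h = 10.0**x
        return na + h - ca * ka / (ka + h) - kw / h

    lo = np.full(pka.shape, -14.0)
    hi = np.full(pka.shape, 0.0)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = balance(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    return -0.5 * (lo + hi)


def oracle_proton(pka, c_acid, v0, c_base, v_added, pkw=13.997):
    """[H+] from the bisection oracle."""
    return 10.0 ** (-oracle_ph(pka, c_acid, v0, c_base, v_added, pkw))


def grid_search_p1(volumes, readings, c_acid, v0, c_base, pkw,
                   center, half_width=1.0, step=1e-4):
    """Exhaustive SSE grid search for the potentiometric pKa.

    Two stages (0.01 then `step` around the coarse minimum); the SSE is
    unimodal in pKa so this equals a full scan at `step` resolution.
    pH values come from the independent bisection oracle.
    """
    volumes = np.asarray(volumes, dtype=float)
    readings = np.asarray(readings, dtype=float)

    def best_on(grid):
        ph = oracle_ph(
            grid[:, None], c_acid, v0, c_base, volumes[None, :], pkw
        )
        sse = np.sum((ph - readings[None, :]) ** 2, axis=1)
        return grid[np.argmin(sse)]

    coarse = np.arange(center - half_width, center + half_width + 0.005, 0.01)
    c0 = best_on(coarse)
    fine = np.arange(c0 - 0.02, c0 + 0.02 + step / 2, step)
    return float(best_on(fine))


def grid_search_hh(ph, absorbance, center, half_width=1.0, step=1e-4):
    """Exhaustive grid search for the Henderson–Hasselbalch pKa.

    For each candidate pKa the model is linear in the two limiting
    absorbances, so they are profiled out by exact 2-parameter least
    squares; the grid covers [center-half_width, center+half_width]
    at `step` resolution (two stages, unimodal SSE).
    """
    ph = np.asarray(ph, dtype=float)
    a = np.asarray(absorbance, dtype=float)

    def sse_of(pka):
        r = 10.0 ** (ph - pka)
        w_acid = 1.0 / (1.0 + r)
        w_base = r / (1.0 + r)
        x = np.column_stack([w_acid, w_base])
        coef, *_ = np.linalg.lstsq(x, a, rcond=None)
        return float(np.sum((x @ coef - a) ** 2))

    def best_on(grid):
        return grid[np.argmin([sse_of(p) for p in grid])]

    coarse = np.arange(center - half_width, center + half_width + 0.005, 0.01)
    c0 = best_on(coarse)
    fine = np.arange(c0 - 0.02, c0 + 0.02 + step / 2, step)
    return float(best_on(fine))
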