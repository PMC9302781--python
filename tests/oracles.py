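"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain scalar loops or closed
forms, independent of the vectorized library code paths it checks.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def scalar_pcnn(s, beta, alpha_t, v_t, weights, n_iter, t0=0.0):
    """Step-by-step scalar PCNN: returns per-iteration (F, L, U, T, O) lists.

    Neighbourhood sums are explicit double loops with zero padding; the
    threshold update uses the previous iteration's output.
    """
    s = [list(map(float, row)) for row in s]
    nrow, ncol = len(s), len(s[0])
    kr, kc = len(weights), len(weights[0])
    cr, cc = kr // 2, kc // 2
    o = [[0.0] * ncol for _ in range(nrow)]
    t = [[float(t0)] * ncol for _ in range(nrow)]
    history = []
    for _ in range(n_iter):
        l = [[0.0] * ncol for _ in range(nrow)]
        for i in range(nrow):
            for j in range(ncol):
                acc = 0.0
                for a in range(kr):
                    for b in range(kc):
                        ii, jj = i + a - cr, j + b - cc
                        if 0 <= ii < nrow and 0 <= jj < ncol:
                            acc += weights[a][b] * o[ii][jj]
                l[i][j] = acc
        u = [[s[i][j] * (1.0 + beta * l[i][j]) for j in range(ncol)]
             for i in range(nrow)]
        o_new = [[1.0 if u[i][j] > t[i][j] else 0.0 for j in range(ncol)]
                 for i in range(nrow)]
        t_new = [[math.exp(-alpha_t) * t[i][j] + v_t * o[i][j]
                  for j in range(ncol)] for i in range(nrow)]
        f = [row[:] for row in s]
        history.append((f, l, u, t_new, o_new))
        o, t = o_new, t_new
    return history


def flood_fill_components(mask):
    """8-connected components by explicit stack-based flood fill."""
    mask = [[bool(v) for v in row] for row in np.asarray(mask)]
    nrow, ncol = len(mask), len(mask[0])
    seen = [[False] * ncol for _ in range(nrow)]
    components = []
    for i in range(nrow):
        for j in range(ncol):
            if not mask[i][j] or seen[i][j]:
                continue
            stack, pixels = [(i, j)], []
            seen[i][j] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < nrow and 0 <= cc < ncol
                                and mask[rr][cc] and not seen[rr][cc]):
                            seen[rr][cc] = True
                            stack.append((rr, cc))
            components.append(pixels)
    return components


def lossy_wavenumber(f, sigma, epsr=1.0):
    """Closed-form k1 via magnitude/phase of the complex permittivity."""
    eps0 = 8.8541878128e-12
    mu0 = 4e-7 * math.pi
    w = 2 * math.pi * f
    tan_delta = sigma / (w * eps0 * epsr)
    mag = (1 + tan_delta**2) ** 0.25
    ang = -0.5 * math.atan(tan_delta)
    return w * math.sqrt(mu0 * eps0 * epsr) * mag * cmath.exp(1j * ang)


def brute_linking(o_prev, weights):
    """Double-loop neighbourhood sum with zero padding."""
    o_prev = np.asarray(o_prev, dtype=float)
    w = np.asarray(weights, dtype=float)
    nrow, ncol = o_prev.shape
    kr, kc = w.shape
    cr, cc = kr // 2, kc // 2
    out = np.zeros_like(o_prev)
    for i in range(nrow):
        for j in range(ncol):
            for a in range(kr):
                for b in range(kc):
                    ii, jj = i + a - cr, j + b - cc
                    if 0 <= ii < nrow and 0 <= jj < ncol:
                        out[i, j] += w[a, b] * o_prev[ii, jj]
    return out
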