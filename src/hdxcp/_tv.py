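"""Exact 1-D total-variation denoising (order-0 L1 trend filtering).

Solves  min_x  0.5 * sum (x_i - y_i)^2  +  lam * sum |x_{i+1} - x_i|
with Condat's direct non-iterative algorithm.  The solution is piecewise
constant, which is what makes it suitable both for extracting change-point
segments from fitted parameter tracks and as the proximal operator inside
the fused-lasso baseline solver.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tv1d_denoise"]


def tv1d_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact solution of the 1-D TV (fused-lasso signal) problem."""
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    N = y.size
    x = np.empty(N, dtype=float)
    if N == 0:
        return x
    if N == 1 or lam == 0.0:
        return y.copy()

    # Condat (2013), direct algorithm
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == N - 1:
            if umin < 0.0:
                x[k0:kminus + 1] = vmin
                k = k0 = kminus = kminus + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            elif umax > 0.0:
                x[k0:kplus + 1] = vmax
                k = k0 = kplus = kplus + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            else:
                x[k0:N] = vmin + umin / (k - k0 + 1)
                return x
        if y[k + 1] + umin < vmin - lam:          # negative jump is forced
            x[k0:kminus + 1] = vmin
            k = k0 = kminus = kplus = kminus + 1
            vmin = y[k]
            vmax = y[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:        # positive jump is forced
            x[k0:kplus + 1] = vmax
            k = k0 = kminus = kplus = kplus + 1
            vmin = y[k] - 2.0 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:                                     # no jump yet: extend segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k
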