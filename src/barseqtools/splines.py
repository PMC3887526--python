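"""Natural cubic spline least-squares smoothing.

The basis is the standard truncated-power natural cubic spline basis with
K knots (K = degrees of freedom, counting the intercept): {1, x, N_1(x),
..., N_{K-2}(x)} where N_k(x) = d_k(x) - d_{K-1}(x) and
d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
Functions in this span are linear beyond the boundary knots, so constants
and straight lines are reproduced exactly.
"""

from __future__ import annotations

import numpy as np


def natural_spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """df knots at quantiles of the distinct x values (boundaries included)."""
    ux = np.unique(np.asarray(x, dtype=float))
    if df < 2:
        raise ValueError("natural spline needs df >= 2")
    if len(ux) < df:
        raise ValueError(f"need at least df={df} distinct x values, got {len(ux)}")
    return np.quantile(ux, np.linspace(0.0, 1.0, df))


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix (len(x), len(knots)) of the natural cubic basis."""
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots, dtype=float)
    K = len(xi)
    cols = [np.ones_like(x), x]

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def smooth_natural_spline(
    x: np.ndarray,
    y: np.ndarray,
    df: int,
    x_eval: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares natural cubic spline fit of y on x, evaluated at
    ``x_eval`` (default: at x). Requires more points than df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < df + 1:
        raise ValueError(f"need at least df+1={df + 1} points, got {len(x)}")
    knots = natural_spline_knots(x, df)
    basis = natural_spline_basis(x, knots)
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    if x_eval is None:
        x_eval = x
    return natural_spline_basis(np.asarray(x_eval, dtype=float), knots) @ coef
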