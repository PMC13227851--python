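"""Cyclic B-spline basis and circulant difference penalty on the weekly circle.

The functional domain is the seven days of the week treated as a circle of
circumference 7 (Saturday wraps to Sunday).  Coefficient curves are expanded
in K periodic cubic B-splines with evenly spaced knots; smoothness is
penalised by a circulant difference penalty whose null space is the constant
function, so an unpenalised flat effect is always representable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cyclic_basis", "cyclic_diff_penalty", "PERIOD"]

PERIOD = 7.0


def _cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline on [-2, 2] (partition of unity over shifts)."""
    at = np.abs(t)
    out = np.zeros_like(at)
    inner = at <= 1
    outer = (at > 1) & (at <= 2)
    out[inner] = (4 - 6 * at[inner] ** 2 + 3 * at[inner] ** 3) / 6
    out[outer] = (2 - at[outer]) ** 3 / 6
    return out


def cyclic_basis(d, K: int = 5, period: float = PERIOD) -> np.ndarray:
    """Evaluate K periodic cubic B-splines at day(s) ``d`` (1..7, cyclic).

    Knots sit at ``j * period / K``; day d maps to position d - 1 so that
    d and d + 7 give identical rows.  Rows sum to 1 (partition of unity).
    """
    if K < 3:
        raise ValueError(f"need K >= 3 cyclic B-splines, got {K}")
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    x = (d_arr - 1.0) % period
    h = period / K
    j = np.arange(K)
    # wrapped signed distance from each knot, in knot units; for small K the
    # cubic support (width 4) can straddle more than one periodic image, so
    # adjacent images are summed as well
    dist = (x[:, None] / h - j[None, :] + K / 2) % K - K / 2
    B = _cubic_bspline(dist) + _cubic_bspline(dist - K) + _cubic_bspline(dist + K)
    return B[0] if np.ndim(d) == 0 else B


def cyclic_diff_penalty(K: int, order: int = 2) -> np.ndarray:
    """Circulant difference penalty S = D'D of the given order on K coefficients.

    Rank K - 1; the null space is the constant coefficient vector.
    """
    if order < 1:
        raise ValueError("difference order must be >= 1")
    D = np.eye(K)
    shift = np.roll(np.eye(K), -1, axis=1)
    diff = shift - np.eye(K)
    for _ in range(order):
        D = diff @ D
    return D.T @ D
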