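"""Series smoothing for derivative-threshold state detection.

The segmentation algorithms in this package (torpor-state annotation, body-mass
period detection) operate on the first derivative of a smoothed trace, so the
smoother is the numerically load-bearing primitive.  The default smoother is a
penalized cubic smoothing spline whose single smoothing parameter ``span`` in
(0, 1] is mapped to the roughness penalty the way R's ``smooth.spline`` maps
``spar``:

    lambda = r · 256^(3·span − 1),   r = tr(XᵀX) / tr(Ω)

with the abscissa scaled to [0, 1], ``X`` the cubic B-spline design matrix and
``Ω`` the second-derivative penalty matrix.  This keeps the conventional
0-to-1 "smoothing parameter" scale while delegating the fit itself to
:func:`scipy.interpolate.make_smoothing_spline`.

A degree-2 local-regression (loess) smoother with span-as-fraction-of-points
semantics is available as ``method="loess"``; it is substantially more biased
around sharp transitions and is not used by the default pipeline.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = ["smooth_series", "smooth_with_derivative", "span_to_lambda"]


def span_to_lambda(x: np.ndarray, span: float) -> float:
    """Map a 0–1 smoothing parameter to a roughness-penalty weight.

    Parameters
    ----------
    x
        Strictly increasing abscissa (original units).
    span
        Smoothing parameter in (0, 1]; larger is smoother.

    Returns
    -------
    float
        Penalty ``lam`` in the units expected by
        :func:`scipy.interpolate.make_smoothing_spline` on the original
        abscissa (the criterion integrates the squared second derivative
        over ``x``, so the scaled-axis penalty is multiplied by range³).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need a 1-d abscissa with at least 5 points")
    span_x = x[-1] - x[0]
    xs = (x - x[0]) / span_x
    t = np.r_[[xs[0]] * 4, xs[1:-1], [xs[-1]] * 4]
    nbasis = len(t) - 4
    tr_xtx = BSpline.design_matrix(xs, t, 3).power(2).sum()
    # tr(Omega): second derivatives of cubic B-splines are piecewise linear,
    # so 3-point Gauss-Legendre per knot interval is exact.
    gl_x, gl_w = np.polynomial.legendre.leggauss(3)
    knots = np.unique(t)
    a, b = knots[:-1], knots[1:]
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    pts = (mid[:, None] + half[:, None] * gl_x).ravel()
    w = (half[:, None] * gl_w).ravel()
    d2 = BSpline(t, np.eye(nbasis), 3)(pts, nu=2)
    tr_omega = (w[:, None] * d2**2).sum()
    r = tr_xtx / tr_omega
    return float(r * 256.0 ** (3.0 * span - 1.0) * span_x**3)


@lru_cache(maxsize=256)
def _lambda_uniform(n: int, span: float) -> float:
    """Cache for the common case of a uniform unit-step grid."""
    return span_to_lambda(np.arange(n, dtype=float), span)


def _fit_spline(x: np.ndarray, y: np.ndarray, span: float) -> BSpline:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("abscissa must be strictly increasing")
    step = np.diff(x)
    if len(x) > 1 and step[0] == 1.0 and np.all(step == 1.0):
        lam = _lambda_uniform(len(x), span)
    else:
        lam = span_to_lambda(x, span)
    return make_smoothing_spline(x, y, lam=lam)


def _loess(x: np.ndarray, y: np.ndarray, span: float, degree: int = 2):
    """Local polynomial regression with tricube weights; returns (fit, slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(degree + 2, int(np.ceil(span * n)))
    fit = np.empty(n)
    slope = np.empty(n)
    order = np.argsort(x)
    xo, yo = x[order], y[order]
    for i in range(n):
        d = np.abs(xo - x[i])
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        dmax = max(d[idx].max(), 1e-12)
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        design = np.vander(xo[idx] - x[i], degree + 1)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], yo[idx] * sw, rcond=None)
        fit[i] = beta[-1]
        slope[i] = beta[-2]
    return fit, slope


def smooth_series(
    y: np.ndarray,
    span: float,
    x: np.ndarray | None = None,
    method: str = "spline",
) -> np.ndarray:
    """Smooth a series; deterministic for fixed input.

    ``span`` is the smoothing parameter in (0, 1].  ``x`` defaults to a
    uniform unit grid (minutes or days).
    """
    fit, _ = smooth_with_derivative(y, span, x=x, method=method)
    return fit


def smooth_with_derivative(
    y: np.ndarray,
    span: float,
    x: np.ndarray | None = None,
    method: str = "spline",
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a series and return ``(fitted, first derivative)`` on ``x``."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if np.any(~np.isfinite(y)):
        raise ValueError("series contains non-finite values; interpolate first")
    if x is None:
        x = np.arange(len(y), dtype=float)
    x = np.asarray(x, dtype=float)
    if method == "spline":
        sp = _fit_spline(x, y, span)
        return sp(x), sp.derivative()(x)
    if method == "loess":
        return _loess(x, y, span)
    raise ValueError(f"unknown smoothing method {method!r}")
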