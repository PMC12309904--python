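"""Smoothing, geometry and numerical-differentiation primitives.

Coordinate time series from pose tracking are smoothed with a natural cubic
smoothing spline whose flexibility is set by its *effective degrees of
freedom* (the trace of the smoother matrix), the same parameterisation used
by R's ``smooth.spline(..., df=)``.  Speeds and accelerations are obtained by
repeated first differences of the smoothed series, and joint angles by the
law of cosines.

The spline is the classic Reinsch/Green–Silverman construction: for knots
``t_1 < ... < t_n`` the fitted values minimise

    sum_i (y_i - f(t_i))^2 + lam * int f''(u)^2 du

over natural cubic splines ``f``.  The fitted values are
``f = y - lam * Q (R + lam Q'Q)^{-1} Q' y`` with the banded matrices Q, R of
Green & Silverman (1994, ch. 2), which keeps every solve O(n).  The smoothing
parameter ``lam`` is found by a monotone root search on
``df(lam) = tr(S_lam)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky_banded, cho_solve_banded
from scipy.optimize import brentq

__all__ = [
    "SmoothedSignal",
    "smooth_series",
    "smooth_at_lambda",
    "effective_df",
    "lambda_for_df",
    "euclidean_distance",
    "vertex_angle",
    "differentiate",
    "derivative_on_grid",
    "DEFAULT_DF",
    "DF_CAP_FRACTION",
]

#: Degrees of freedom used for coordinate smoothing at 1000 frames/s.
DEFAULT_DF = 80.0

#: The df target is capped at this fraction of the series length so that the
#: request stays meaningful for short series (df = 80 is undefined at n < 80).
DF_CAP_FRACTION = 0.25


# ---------------------------------------------------------------------------
# Natural cubic smoothing spline (Reinsch algorithm, banded)
# ---------------------------------------------------------------------------

def _qr_bands(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Banded representations of the Green–Silverman Q (n x n-2) and R.

    Returns ``(q_cols, r_band)`` where ``q_cols[k, c]`` (k = 0, 1, 2) holds the
    three non-zeros of column c of Q (rows c, c+1, c+2) and ``r_band`` is R in
    upper-diagonal-ordered form for the banded Cholesky routines.
    """
    h = np.diff(t)
    if np.any(h <= 0):
        raise ValueError("t must be strictly increasing")
    n = t.size
    ha = h[: n - 2]          # spacing left of each interior knot
    hb = h[1: n - 1]         # spacing right of each interior knot
    q_cols = np.empty((3, n - 2))
    q_cols[0] = 1.0 / ha
    q_cols[1] = -1.0 / ha - 1.0 / hb
    q_cols[2] = 1.0 / hb
    r_band = np.zeros((2, n - 2))
    r_band[1] = (ha + hb) / 3.0
    r_band[0, 1:] = hb[:-1] / 6.0
    return q_cols, r_band


def _qt_y(q_cols: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Q' y for Q given in 3-diagonal column form."""
    return q_cols[0] * y[:-2] + q_cols[1] * y[1:-1] + q_cols[2] * y[2:]


def _q_c(q_cols: np.ndarray, c: np.ndarray, n: int) -> np.ndarray:
    """Q c for Q given in 3-diagonal column form."""
    out = np.zeros(n)
    out[:-2] += q_cols[0] * c
    out[1:-1] += q_cols[1] * c
    out[2:] += q_cols[2] * c
    return out


def _system_band(q_cols: np.ndarray, r_band: np.ndarray, lam: float) -> np.ndarray:
    """Upper band form (bandwidth 2) of B = R + lam * Q'Q."""
    m = q_cols.shape[1]
    d0 = q_cols[0] ** 2 + q_cols[1] ** 2 + q_cols[2] ** 2
    d1 = q_cols[1, :-1] * q_cols[0, 1:] + q_cols[2, :-1] * q_cols[1, 1:]
    d2 = q_cols[2, :-2] * q_cols[0, 2:]
    band = np.zeros((3, m))
    band[2] = r_band[1] + lam * d0
    band[1, 1:] = r_band[0, 1:] + lam * d1
    band[0, 2:] = lam * d2
    return band


def _qtq_dense(q_cols: np.ndarray) -> np.ndarray:
    m = q_cols.shape[1]
    qtq = np.zeros((m, m))
    d0 = q_cols[0] ** 2 + q_cols[1] ** 2 + q_cols[2] ** 2
    d1 = q_cols[1, :-1] * q_cols[0, 1:] + q_cols[2, :-1] * q_cols[1, 1:]
    d2 = q_cols[2, :-2] * q_cols[0, 2:]
    idx = np.arange(m)
    qtq[idx, idx] = d0
    qtq[idx[:-1], idx[:-1] + 1] = d1
    qtq[idx[:-1] + 1, idx[:-1]] = d1
    qtq[idx[:-2], idx[:-2] + 2] = d2
    qtq[idx[:-2] + 2, idx[:-2]] = d2
    return qtq


def effective_df(t: np.ndarray, lam: float) -> float:
    """Trace of the smoother matrix S_lam = (I + lam K)^{-1}.

    Uses tr(S) = n - lam * tr((R + lam Q'Q)^{-1} Q'Q), which only needs one
    banded factorisation and a banded-matrix solve.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    q_cols, r_band = _qr_bands(t)
    band = _system_band(q_cols, r_band, lam)
    cb = cholesky_banded(band)
    x = cho_solve_banded((cb, False), _qtq_dense(q_cols))
    return float(n - lam * np.trace(x))


def smooth_at_lambda(t: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Fitted values of the natural cubic smoothing spline at penalty ``lam``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if lam == 0:
        return y.copy()
    q_cols, r_band = _qr_bands(t)
    band = _system_band(q_cols, r_band, lam)
    cb = cholesky_banded(band)
    c = cho_solve_banded((cb, False), _qt_y(q_cols, y))
    return y - lam * _q_c(q_cols, c, t.size)


# cache of solved smoothing parameters keyed by the series geometry; every
# coordinate series of a bout shares one (n, spacing, df) triple.
_LAMBDA_CACHE: dict[tuple[int, float, float], tuple[float, float]] = {}


def lambda_for_df(t: np.ndarray, target_df: float) -> tuple[float, float]:
    """Penalty whose effective df matches ``target_df``; returns (lam, df).

    ``df(lam)`` decreases monotonically from n (interpolation) to 2 (straight
    line), so the root is bracketed on a log scale and found with Brent's
    method.
    """
    t = np.asarray(t, dtype=float)
    n = t.size
    if not 2 <= target_df <= n:
        raise ValueError(f"target df must lie in [2, {n}]")
    h = np.diff(t)
    uniform = float(np.max(h) - np.min(h)) < 1e-9 * float(np.mean(h))
    key = (n, round(float(h[0]), 12), round(float(target_df), 6)) if uniform else None
    if key is not None and key in _LAMBDA_CACHE:
        return _LAMBDA_CACHE[key]
    if target_df >= n - 1e-9:
        return 0.0, float(n)

    # scale-aware bracket: lam ~ span^3 sets df near its lower limit
    span = float(t[-1] - t[0])
    lo, hi = math.log10(span ** 3) - 18.0, math.log10(span ** 3) + 12.0

    def f(log_lam: float) -> float:
        return effective_df(t, 10.0 ** log_lam) - target_df

    flo, fhi = f(lo), f(hi)
    while flo < 0:                      # pragma: no cover - defensive bracket
        lo -= 4.0
        flo = f(lo)
    while fhi > 0:                      # pragma: no cover
        hi += 4.0
        fhi = f(hi)
    log_lam = brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)
    lam = 10.0 ** log_lam
    out = (lam, effective_df(t, lam))
    if key is not None:
        _LAMBDA_CACHE[key] = out
    return out


def smooth_series(
    t: np.ndarray,
    y: np.ndarray,
    target_df: float = DEFAULT_DF,
    cap_fraction: float = DF_CAP_FRACTION,
) -> tuple[np.ndarray, float]:
    """Smooth ``y(t)`` with a cubic smoothing spline at a given effective df.

    Parameters
    ----------
    t, y
        Sample times (strictly increasing) and values.
    target_df
        Requested trace of the smoother matrix.  The realised target is
        ``min(target_df, cap_fraction * n)`` (never below 2) so that short
        series are not fitted with more flexibility than they can support.

    Returns
    -------
    (smoothed, effective_df)
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 samples to smooth")
    if target_df < 2:
        raise ValueError("target df must be at least 2")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    df_eff_target = max(2.0, min(float(target_df), cap_fraction * n))
    lam, df = lambda_for_df(t, df_eff_target)
    return smooth_at_lambda(t, y, lam), df


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def euclidean_distance(a, b) -> float:
    """Distance between two 2-D points (cm in, cm out)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.hypot(*(a - b).T)) if a.ndim == 1 else np.hypot(
        a[..., 0] - b[..., 0], a[..., 1] - b[..., 1]
    )


def vertex_angle(a, b, c) -> float:
    """Angle at vertex ``a`` between rays to ``b`` and ``c``, in degrees.

    Computed from the three pairwise distances by the law of cosines; the
    arccos argument is clamped to [-1, 1] to absorb rounding on nearly
    degenerate triangles.  Defined for 0 <= angle <= 180.
    """
    d_ab = euclidean_distance(a, b)
    d_ac = euclidean_distance(a, c)
    d_bc = euclidean_distance(b, c)
    if np.any(np.asarray(d_ab) == 0) or np.any(np.asarray(d_ac) == 0):
        raise ValueError("vertex coincides with an endpoint; angle undefined")
    cos_arg = (d_ab ** 2 + d_ac ** 2 - d_bc ** 2) / (2.0 * d_ab * d_ac)
    cos_arg = np.clip(cos_arg, -1.0, 1.0)
    out = np.degrees(np.arccos(cos_arg))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------

def differentiate(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First differences dy/dt, timestamped at interval midpoints."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    dt = np.diff(t)
    return 0.5 * (t[:-1] + t[1:]), np.diff(y) / dt


def derivative_on_grid(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """dy/dt re-interpolated from interval midpoints back onto ``t``.

    Keeps the derivative on the same time base as the signal so event windows
    can index both consistently; the end samples take the nearest midpoint
    value.
    """
    t_mid, d = differentiate(t, y)
    return np.interp(t, t_mid, d)


@dataclass
class SmoothedSignal:
    """A smoothed kinematic signal with first and second derivatives.

    ``d1``/``d2`` live on midpoint grids (lengths n-1, n-2); ``d1_grid`` and
    ``d2_grid`` are the same derivatives re-aligned onto ``t`` for event
    logic.
    """

    t: np.ndarray
    value: np.ndarray
    effective_df: float
    t_d1: np.ndarray = field(init=False)
    d1: np.ndarray = field(init=False)
    t_d2: np.ndarray = field(init=False)
    d2: np.ndarray = field(init=False)
    d1_grid: np.ndarray = field(init=False)
    d2_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t_d1, self.d1 = differentiate(self.t, self.value)
        self.t_d2, self.d2 = differentiate(self.t_d1, self.d1)
        self.d1_grid = np.interp(self.t, self.t_d1, self.d1)
        self.d2_grid = np.interp(self.t, self.t_d2, self.d2)

    @classmethod
    def from_raw(
        cls,
        t: np.ndarray,
        y: np.ndarray,
        target_df: float = DEFAULT_DF,
        smooth: bool = True,
    ) -> "SmoothedSignal":
        if smooth:
            value, df = smooth_series(t, y, target_df)
        else:
            value, df = np.asarray(y, dtype=float), float(len(y))
        return cls(t=np.asarray(t, dtype=float), value=value, effective_df=df)
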