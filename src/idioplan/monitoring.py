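"""Process- and outcome-monitoring statistics.

Moving-window *dynamic complexity* flags critical instabilities that tend
to precede sudden symptom shifts: it is the product of a fluctuation
component F (how intensely the series swings between turning points,
normalized so maximal full-range alternation gives 1) and a distribution
component D (how evenly the window's values cover the response scale).
Recurrence matrices, locally weighted trend curves with pointwise 95%
confidence bands, and weekly percent-change outcome scores complete the
monitoring toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .errors import InvalidWindowError, ValidationError

__all__ = [
    "ComplexitySeries",
    "RecurrenceMatrix",
    "SmoothedSeries",
    "dynamic_complexity",
    "rescale_complexity",
    "recurrence_matrix",
    "loess_ci",
    "weekly_change",
]


@dataclass
class ComplexitySeries:
    """Per-window dynamic complexity C = F * D, causally aligned: the value
    at position i describes the window ending at observation i."""

    values: np.ndarray  # C per window
    fluctuation: np.ndarray  # F component
    distribution: np.ndarray  # D component
    window: int
    scale_min: float
    scale_max: float
    positions: np.ndarray  # end index of each window


@dataclass
class RecurrenceMatrix:
    """T x T Euclidean distances between assessment points."""

    d: np.ndarray


@dataclass
class SmoothedSeries:
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float


def _points_of_return(w: np.ndarray) -> list[int]:
    """Window indices of the first point, last point, and interior turning
    points (direction reversals; a plateau's turning point is its start)."""
    m = len(w)
    pts = [0]
    last_sign = 0
    last_end = 0
    for i in range(1, m):
        s = int(np.sign(w[i] - w[i - 1]))
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign and last_end not in pts:
            pts.append(last_end)
        last_sign = s
        last_end = i
    if pts[-1] != m - 1:
        pts.append(m - 1)
    return pts


def dynamic_complexity(
    series: np.ndarray,
    m: int = 7,
    smin: float | None = None,
    smax: float | None = None,
) -> ComplexitySeries:
    """Dynamic complexity of a univariate series over moving windows.

    Per window of width ``m`` on a scale of range R = smax - smin:

    * F sums |Δy| / Δsteps over successive points of return and divides by
      R·(m−1); alternation between the scale bounds at every step gives 1,
      a flat window gives 0.
    * D sorts the window, takes the m−1 gaps g_i between successive sorted
      values, and is max(0, 1 − Σ|g_i − R/(m−1)| / R); values spread evenly
      over the full scale give 1.
    * C = F·D, in [0, 1].
    """
    y = np.asarray(series, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValidationError("series must not contain missing values")
    n = len(y)
    if m < 2:
        raise InvalidWindowError("window must be >= 2")
    if n < m:
        raise InvalidWindowError(f"series length {n} shorter than window {m}")
    if smin is None:
        smin = float(np.min(y))
    if smax is None:
        smax = float(np.max(y))
    R = smax - smin
    if R <= 0:
        raise ValidationError("smax must exceed smin")
    n_win = n - m + 1
    F = np.zeros(n_win)
    D = np.zeros(n_win)
    uniform_gap = R / (m - 1)
    for w0 in range(n_win):
        w = y[w0 : w0 + m]
        pts = _points_of_return(w)
        s = 0.0
        for a, b in zip(pts, pts[1:]):
            s += abs(w[b] - w[a]) / (b - a)
        F[w0] = s / (R * (m - 1))
        gaps = np.diff(np.sort(w))
        D[w0] = max(0.0, 1.0 - float(np.sum(np.abs(gaps - uniform_gap))) / R)
    C = F * D
    return ComplexitySeries(
        values=C,
        fluctuation=F,
        distribution=D,
        window=m,
        scale_min=smin,
        scale_max=smax,
        positions=np.arange(m - 1, n),
    )


def rescale_complexity(
    cs: ComplexitySeries, ymin: float, ymax: float
) -> np.ndarray:
    """Affinely map complexity from [0, 1] onto the raw plot's value range,
    so the complexity curve can be overlaid on the symptom curve."""
    if not ymax > ymin:
        raise ValidationError("ymax must exceed ymin")
    return ymin + cs.values * (ymax - ymin)


def recurrence_matrix(points: np.ndarray) -> RecurrenceMatrix:
    """Time x time Euclidean distance matrix (absolute differences in the
    univariate case); recurring states show up as near-zero off-diagonal
    regions."""
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.isnan(x).any():
        raise ValidationError("series must not contain missing values")
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 points")
    return RecurrenceMatrix(d=squareform(pdist(x, metric="euclidean")))


def loess_ci(
    series: np.ndarray, span: float = 0.75, level: float = 0.95
) -> SmoothedSeries:
    """Locally weighted linear regression (tricube kernel) with pointwise CI.

    The smoother is evaluated at every observation index; the confidence
    band uses the global residual variance estimate
    sigma^2 = RSS / (n − 2 tr(L) + tr(L'L)) and the norm of each local
    weight vector, assuming locally Gaussian residuals.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = len(y)
    if n < 5:
        raise ValidationError("need at least 5 points to smooth")
    if np.isnan(y).any():
        raise ValidationError("series must not contain missing values")
    q = int(np.ceil(span * n))
    if q < 3:
        raise InvalidWindowError(f"span {span} gives {q} local points; need >= 3")
    q = min(q, n)
    x = np.arange(n, dtype=float)
    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[q - 1]
        if h == 0:
            h = 1.0
        u = np.clip(d / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        # local linear fit: l_i = e1' (X'WX)^-1 X'W with X = [1, x - x_i]
        xc = x - x[i]
        s0, s1, s2 = np.sum(w), np.sum(w * xc), np.sum(w * xc**2)
        det = s0 * s2 - s1**2
        if det <= 1e-12:
            L[i] = w / s0
        else:
            L[i] = (s2 * w - s1 * w * xc) / det
    fitted = L @ y
    resid = y - fitted
    nu1 = np.trace(L)
    nu2 = np.sum(L * L)
    dof = max(n - 2 * nu1 + nu2, 1.0)
    sigma2 = float(resid @ resid) / dof
    zcrit = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(sigma2 * np.sum(L**2, axis=1))
    return SmoothedSeries(
        fitted=fitted,
        lower=fitted - zcrit * se,
        upper=fitted + zcrit * se,
        span=span,
    )


def weekly_change(outcomes: np.ndarray) -> np.ndarray:
    """Week-over-week percent change; negative values mean symptom
    reduction."""
    y = np.asarray(outcomes, dtype=float).ravel()
    if len(y) < 2:
        raise ValidationError("need at least 2 weekly scores")
    prev = y[:-1]
    if np.any(prev == 0):
        raise ValidationError("undefined change: previous weekly score is zero")
    return 100.0 * (y[1:] - prev) / prev
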