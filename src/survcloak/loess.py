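"""Local polynomial regression (LOESS) with automated span selection.

At each target point the smoother fits a weighted least-squares polynomial
of degree 1 or 2 over the q = ceil(span * n) nearest neighbours on the
time axis, with tricube weights w(u) = (1 - |u|^3)^3 on the scaled
distance u = d / d_max.  Because the fit is linear in the responses, a hat
matrix L exists with fitted = L @ y; its trace is the smoother's effective
number of parameters.

The span is chosen automatically by minimising the corrected Akaike
information criterion in the Hurvich-Simonoff-Tsai form for nonparametric
smoothers,

    AICc = log(sigma^2) + 1 + 2 (nu + 1) / (n - nu - 2),

with sigma^2 = RSS / n and nu = trace(L).  AICc penalises effective model
size more sharply than AIC at small n, which suits the short grids
(one point per distinct observed time) these smoothers see.

The search over spans exploits a structural fact: the fit depends on the
span only through the window size q, so AICc is piecewise constant in the
span with breaks at q / n.  Evaluating one candidate span per attainable q
is therefore an exact exhaustive minimisation — cheaper and strictly more
reliable than golden-section search on a piecewise-constant objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DegenerateFitError, SpanSelectionError, ValidationError

__all__ = ["LoessFit", "loess_fit", "aicc", "select_span", "LoessSmoother"]

_SIGMA2_FLOOR = 1e-300  # guard: exact fits must not crash the log


@dataclass
class LoessFit:
    """A fitted local-regression smoother (linear in y)."""

    span: float
    degree: int
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    hat_trace: float
    sigma2: float
    n: int

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.fitted

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _local_row(x: np.ndarray, x0: float, q: int, degree: int) -> Tuple[np.ndarray, np.ndarray]:
    """Indices and hat-matrix row of the local fit at target x0.

    The row r satisfies fitted(x0) = r @ y[idx] for any response y.
    """
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    h = d[idx].max()
    if h == 0.0:
        raise DegenerateFitError(f"all {q} window points coincide at x={x0}: zero bandwidth")
    w = _tricube(d[idx] / h)
    pos = w > 0
    if np.unique(x[idx][pos]).size < degree + 1:
        raise DegenerateFitError(
            f"window at x={x0} has fewer than {degree + 1} distinct x values with positive weight"
        )
    z = x[idx] - x0
    A = np.vander(z, degree + 1, increasing=True)  # columns 1, z, z^2
    Aw = A * w[:, None]
    M = A.T @ Aw
    try:
        # first row of (A' W A)^{-1} A' W — the value of the local polynomial at z = 0
        beta_rows = np.linalg.solve(M, Aw.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"singular local design at x={x0}") from exc
    return idx, beta_rows[0]


def loess_fit(x: Sequence[float], y: Sequence[float], span: float, degree: int = 1) -> LoessFit:
    """Fit the LOESS smoother at every data point.

    Parameters
    ----------
    x : sorted (non-decreasing) predictor values, here usually times.
    y : responses, here survival proportions.
    span : fraction of points in each local window, in (0, 1].
    degree : local polynomial degree, 1 or 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if degree not in (1, 2):
        raise ValidationError(f"degree must be 1 or 2, got {degree}")
    if not 0.0 < span <= 1.0:
        raise ValidationError(f"span must lie in (0, 1], got {span}")
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d and of equal length")
    if n < degree + 2:
        raise ValidationError(f"need at least degree + 2 = {degree + 2} points, got {n}")
    if np.any(np.diff(x) < 0):
        raise ValidationError("x must be sorted non-decreasing")

    q = min(n, max(degree + 1, math.ceil(span * n)))
    L = np.zeros((n, n))
    for i in range(n):
        idx, row = _local_row(x, x[i], q, degree)
        L[i, idx] = row
    fitted = L @ y
    trace = float(np.trace(L))
    rss = float(np.sum((y - fitted) ** 2))
    denom = n - trace
    sigma2 = rss / denom if denom > 0 else float("inf")
    return LoessFit(span=span, degree=degree, x=x, y=y, fitted=fitted, hat_trace=trace, sigma2=sigma2, n=n)


def aicc(fit: LoessFit) -> float:
    """Corrected AIC of a smoother fit (Hurvich-Simonoff-Tsai form).

    Uses the maximum-likelihood variance RSS / n.  Raises
    :class:`DegenerateFitError` when n - nu - 2 <= 0 (the span is too
    small for the sample size to support the penalty term).
    """
    nu = fit.hat_trace
    denom = fit.n - nu - 2.0
    if denom <= 0:
        raise DegenerateFitError(f"AICc undefined: n - trace - 2 = {denom:.3g} <= 0 (span too small for n={fit.n})")
    sigma2_ml = max(fit.rss / fit.n, _SIGMA2_FLOOR)
    return float(np.log(sigma2_ml) + 1.0 + 2.0 * (nu + 1.0) / denom)


def _candidate_spans(n: int, interval: Tuple[float, float], resolution: Optional[float]) -> np.ndarray:
    lo, hi = interval
    if not 0.0 < lo < hi <= 1.0:
        raise ValidationError(f"search interval must satisfy 0 < lo < hi <= 1, got {interval}")
    if resolution is not None:
        return np.arange(lo, hi + 1e-12, resolution)
    # one span per attainable window size q = ceil(span * n): the objective
    # is constant between breaks, so this is an exact exhaustive search
    q_lo = math.ceil(lo * n)
    q_hi = math.ceil(hi * n)
    return np.array([min(q / n, hi) for q in range(max(q_lo, 1), q_hi + 1)])


def select_span(
    x: Sequence[float],
    y: Sequence[float],
    degree: int = 1,
    interval: Tuple[float, float] = (0.05, 0.95),
    resolution: Optional[float] = None,
) -> Tuple[float, LoessFit]:
    """Choose the span minimising AICc; returns ``(span, fit)``.

    By default every attainable window size within ``interval`` is
    evaluated (exact minimisation; see module docstring).  Passing a
    ``resolution`` switches to a plain grid, useful for cross-checks.
    Deterministic for fixed inputs; candidates yielding degenerate fits
    are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best: Optional[Tuple[float, float, LoessFit]] = None
    for span in _candidate_spans(x.size, interval, resolution):
        try:
            fit = loess_fit(x, y, float(span), degree)
            crit = aicc(fit)
        except (DegenerateFitError, ValidationError):
            continue
        if best is None or crit < best[0]:
            best = (crit, float(span), fit)
    if best is None:
        raise SpanSelectionError(
            f"no span in {interval} yields a valid degree-{degree} fit for n={x.size}; "
            "widen the interval minimum or provide more data"
        )
    return best[1], best[2]


class LoessSmoother(RegressorMixin, BaseEstimator):
    """LOESS smoother with optional automated span selection.

    Parameters
    ----------
    span : 'auto' or float in (0, 1]
        ``'auto'`` minimises AICc over all attainable window sizes within
        ``span_interval``; a float forces that span.
    degree : int, 1 or 2
        Local polynomial degree.
    span_interval : (lo, hi)
        Search interval used when ``span='auto'``.

    Attributes
    ----------
    span_ : float            chosen (or forced) span
    fit_ : LoessFit          full fit object (hat trace, residual variance)
    aicc_ : float            AICc of the retained fit
    fitted_values_ : ndarray fitted values in the original input order
    """

    def __init__(self, span="auto", degree: int = 1, span_interval: Tuple[float, float] = (0.05, 0.95)):
        self.span = span
        self.degree = degree
        self.span_interval = span_interval

    def fit(self, X, y):
        x = np.ravel(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        if self.span == "auto":
            self.span_, self.fit_ = select_span(xs, ys, self.degree, self.span_interval)
        else:
            self.fit_ = loess_fit(xs, ys, float(self.span), self.degree)
            self.span_ = float(self.span)
        self.aicc_ = aicc(self.fit_)
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        self.fitted_values_ = self.fit_.fitted[inv]
        return self

    def predict(self, X):
        if not hasattr(self, "fit_"):
            raise ValidationError("smoother is not fitted")
        x0s = np.ravel(np.asarray(X, dtype=float))
        f = self.fit_
        q = min(f.n, max(f.degree + 1, math.ceil(f.span * f.n)))
        out = np.empty(x0s.size)
        for j, x0 in enumerate(x0s):
            idx, row = _local_row(f.x, float(x0), q, f.degree)
            out[j] = row @ f.y[idx]
        return out
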