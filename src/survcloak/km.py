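"""Product-limit (Kaplan-Meier) estimation and step-function evaluation.

The estimator is the standard nonparametric maximum-likelihood estimate of
the survival function S(t) = Pr(T > t) under independent right censoring:
at each distinct observed time t_i with d_i events among n_i subjects at
risk, the curve multiplies in a factor (1 - d_i / n_i).  Censoring-only
times are listed on the curve as well (with a factor of 1), because the
smoothing step downstream operates on the full grid of observed times.

Ties between events and censorings at the same time follow the standard
convention: events are deemed to occur first, so censored subjects still
count in the risk set at their own time.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import PrivacyCurve, SurvivalCurve, SurvivalDataset
from .errors import ValidationError

__all__ = ["fit_km", "eval_curve", "step_points", "KaplanMeierEstimator"]


def fit_km(data: SurvivalDataset) -> SurvivalCurve:
    """Fit the product-limit survival curve for one dataset.

    Returns a :class:`SurvivalCurve` with one entry per distinct observed
    time (event or censoring).  Permutation invariant in the record order.
    """
    if len(data) == 0:
        raise ValidationError("cannot fit a survival curve on an empty dataset")
    n = len(data)
    times, inverse = np.unique(data.times, return_inverse=True)
    d = np.bincount(inverse, weights=data.events.astype(float)).astype(np.int64)
    c = np.bincount(inverse, weights=(1 - data.events).astype(float)).astype(np.int64)
    # at risk just before t: everyone with observed time >= t
    sorted_times = np.sort(data.times)
    n_risk = n - np.searchsorted(sorted_times, times, side="left")
    surv = np.cumprod(1.0 - d / n_risk)
    return SurvivalCurve(times, n_risk, d, c, surv, n_total=n)


def eval_curve(curve: Union[SurvivalCurve, PrivacyCurve], t) -> np.ndarray:
    """Evaluate a curve at time(s) ``t``.

    Raw curves (and ``method='none'`` releases, which are staircase
    samples) use right-continuous step interpolation with S = 1 before the
    first listed time.  Smoothed/anonymised releases are no longer
    staircases and use linear interpolation between points, constant
    beyond the ends.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValidationError("evaluation times must be >= 0")
    stepwise = isinstance(curve, SurvivalCurve) or curve.method == "none"
    if stepwise:
        idx = np.searchsorted(curve.times, t_arr, side="right") - 1
        out = np.where(idx >= 0, curve.surv[np.clip(idx, 0, None)], 1.0)
    else:
        out = np.interp(t_arr, curve.times, curve.surv)
    return out if np.ndim(t) else float(out[0])


def step_points(curve: SurvivalCurve, include_censor_marks: bool = False):
    """Staircase vertices for plotting, starting at (0, 1).

    Returns ``(vertices, censor_marks)``: vertices trace the step function
    through every survival drop; censor marks are (t, S(t)) pairs at
    censoring times, returned only when the flag is set (they are
    disclosive and suppressed in privacy releases).
    """
    if len(curve) == 0:
        raise ValidationError("curve must be non-empty")
    verts = [(0.0, 1.0)]
    prev = 1.0
    for t, s in zip(curve.times, curve.surv):
        if s != prev:
            verts.append((float(t), prev))
            verts.append((float(t), float(s)))
            prev = float(s)
    censor_marks = []
    if include_censor_marks:
        for t in curve.censor_times:
            censor_marks.append((float(t), eval_curve(curve, float(t))))
    return np.asarray(verts), np.asarray(censor_marks).reshape(-1, 2)


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator with a scikit-learn style interface.

    ``fit`` accepts either a :class:`SurvivalDataset`, or an (n, 2) array
    of ``[time, event]`` columns, or separate ``X`` (times) and ``y``
    (event indicators).  ``predict`` evaluates the fitted step function.

    Attributes
    ----------
    curve_ : SurvivalCurve
        The fitted curve.
    n_subjects_ : int
        Number of subjects used in the fit.
    """

    def fit(self, X, y=None):
        if isinstance(X, SurvivalDataset):
            data = X
        else:
            X = np.asarray(X, dtype=float)
            if y is not None:
                data = SurvivalDataset(np.ravel(X), np.asarray(y))
            elif X.ndim == 2 and X.shape[1] == 2:
                data = SurvivalDataset(X[:, 0], X[:, 1].astype(np.int64))
            else:
                raise ValidationError("fit needs a SurvivalDataset, an (n,2) [time,event] array, or X=times with y=events")
        self.curve_ = fit_km(data)
        self.n_subjects_ = len(data)
        return self

    def predict(self, T):
        if not hasattr(self, "curve_"):
            raise ValidationError("estimator is not fitted")
        return eval_curve(self.curve_, np.asarray(T, dtype=float))
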