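"""Independent oracles and tiny data builders shared across test modules.

Everything here is deliberately written by a different route than the
library code it checks: the product-limit oracle enumerates risk sets
subject by subject, the local-regression oracle goes through
``np.polyfit`` on explicitly constructed tricube weights, and the
staircase evaluator walks the steps directly.
"""

from __future__ import annotations

import math

import numpy as np

from survcloak import SurvivalDataset


def km_oracle(times, events):
    """Brute-force product-limit estimate by direct risk-set enumeration.

    Returns (times, n_risk, n_event, n_censor, surv) lists over the
    distinct observed times.
    """
    times = list(map(float, times))
    events = list(map(int, events))
    uniq = sorted(set(times))
    out_t, out_r, out_d, out_c, out_s = [], [], [], [], []
    surv = 1.0
    for t in uniq:
        at_risk = sum(1 for T in times if T >= t)
        d = sum(1 for T, e in zip(times, events) if T == t and e == 1)
        c = sum(1 for T, e in zip(times, events) if T == t and e == 0)
        surv = surv * (1.0 - d / at_risk)
        out_t.append(t)
        out_r.append(at_risk)
        out_d.append(d)
        out_c.append(c)
        out_s.append(surv)
    return out_t, out_r, out_d, out_c, out_s


def loess_point_oracle(x, y, span, degree, i):
    """Fitted value at x[i] via an explicitly built weighted LS problem.

    Builds the tricube weight vector over the q nearest neighbours and
    solves the polynomial fit with ``np.polyfit`` (QR-based), independent
    of the library's normal-equations route.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    q = min(n, max(degree + 1, math.ceil(span * n)))
    d = np.abs(x - x[i])
    idx = np.argsort(d, kind="stable")[:q]
    h = d[idx].max()
    u = d[idx] / h
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
    coeffs = np.polyfit(x[idx] - x[i], y[idx], degree, w=np.sqrt(w))
    return coeffs[-1]  # constant term = value at the target


def staircase_eval(step_times, step_surv, t):
    """Right-continuous step evaluation by linear scan (no searchsorted)."""
    value = 1.0
    for st, ss in zip(step_times, step_surv):
        if st <= t:
            value = ss
        else:
            break
    return value


def random_dataset(rng, n=None, max_n=20, censor_prob=0.4, tie_prob=0.3):
    """Small random dataset with ties and mixed censoring for oracle tests."""
    if n is None:
        n = int(rng.integers(1, max_n + 1))
    times = np.round(rng.uniform(0, 10, n), 0 if rng.random() < tie_prob else 3)
    events = (rng.random(n) > censor_prob).astype(int)
    return SurvivalDataset(times, events, name="random")


def random_staircase(rng, n_steps=None):
    """A valid survival staircase sample: x ascending, y non-increasing in [0,1]."""
    if n_steps is None:
        n_steps = int(rng.integers(3, 40))
    x = np.sort(rng.uniform(0, 100, n_steps))
    drops = rng.dirichlet(np.ones(n_steps)) * rng.uniform(0.3, 1.0)
    y = 1.0 - np.cumsum(drops)
    return np.column_stack([x, np.clip(y, 0.0, 1.0)])
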