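"""Point-cloud anonymisation mechanisms.

Two mechanisms besides smoothing are provided for comparison:

* **Probabilistic** — each selected coordinate v is perturbed to
  v * (1 + p/100 * eps) with eps i.i.d. standard normal under a stated
  seed, then a monotonicity repair restores a valid survival staircase
  (time strictly increasing, survival non-increasing within [0, 1]).
* **Deterministic** — each point is replaced by the centroid of its k
  nearest neighbours in the (time, survival) plane, the point itself
  included.  On skewed survival data this pulls points toward the centre
  of mass, which is exactly why it trades utility poorly.

Both are deterministic given their parameters (and seed).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import NoiseSpec
from .errors import ValidationError

__all__ = [
    "probabilistic_anonymize",
    "deterministic_anonymize",
    "monotone_repair",
    "ProbabilisticAnonymizer",
    "DeterministicAnonymizer",
]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("point coordinates must be finite")
    return pts


def monotone_repair(x: np.ndarray, y: np.ndarray, repair_x: bool = True) -> tuple:
    """Project perturbed staircase samples back onto a valid shape.

    x is sorted (stably) and residual ties are broken by the minimal
    representable upward offset; y is replaced by its running minimum and
    clipped to [0, 1].  The running minimum is the cheapest projection
    that preserves right-continuity of the staircase reading.
    """
    x = np.array(x, dtype=float)
    y = np.array(y, dtype=float)
    if repair_x:
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        for i in range(1, x.size):
            if x[i] <= x[i - 1]:
                x[i] = np.nextafter(x[i - 1], np.inf)
    y = np.minimum.accumulate(np.clip(y, 0.0, 1.0))
    return x, y


def probabilistic_anonymize(points, spec: NoiseSpec) -> np.ndarray:
    """Add seeded percentage-of-value Gaussian noise, then repair.

    Input must be a valid staircase sample: x ascending, y non-increasing.
    Output satisfies x strictly increasing, y non-increasing in [0, 1].
    Bit-reproducible for a fixed ``spec.seed``: x-axis noise (when
    selected) is drawn before y-axis noise.
    """
    pts = _as_points(points)
    x, y = pts[:, 0].copy(), pts[:, 1].copy()
    if np.any(np.diff(x) < 0) or np.any(np.diff(y) > 0):
        raise ValidationError("input points must be sorted by x ascending with y non-increasing")
    rng = np.random.default_rng(spec.seed)
    scale = spec.percentage / 100.0
    perturb_x = "x" in spec.axes
    if perturb_x:
        x = x * (1.0 + scale * rng.standard_normal(x.size))
    if "y" in spec.axes:
        y = y * (1.0 + scale * rng.standard_normal(y.size))
    x, y = monotone_repair(x, y, repair_x=perturb_x)
    return np.column_stack([x, y])


def deterministic_anonymize(points, k: int, include_self: bool = True) -> np.ndarray:
    """Replace each point by the centroid of its k nearest neighbours.

    Distances are Euclidean in the raw (x, y) plane (no axis
    standardisation); ties are broken by lower input index so the result
    is deterministic.  With ``include_self`` (default, the natural reading
    of a k-sized cluster containing the point) k = 1 is the identity and
    k = n collapses everything onto the global centroid.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    if not include_self:
        np.fill_diagonal(dist, np.inf)
    # stable argsort => equidistant neighbours resolved by lower index
    neighbours = np.argsort(dist, axis=1, kind="stable")[:, :k]
    return pts[neighbours].mean(axis=1)


class ProbabilisticAnonymizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`probabilistic_anonymize`.

    Each ``transform`` call re-derives its noise stream from
    ``random_state``, so repeated calls on the same input are identical.
    """

    def __init__(self, percentage: float = 5.0, axes=("x", "y"), random_state: int = 0):
        self.percentage = percentage
        self.axes = axes
        self.random_state = random_state

    def fit(self, X, y=None):
        _as_points(X)
        return self

    def transform(self, X):
        spec = NoiseSpec(self.percentage, tuple(self.axes), self.random_state)
        return probabilistic_anonymize(X, spec)


class DeterministicAnonymizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`deterministic_anonymize`."""

    def __init__(self, k: int = 5, include_self: bool = True):
        self.k = k
        self.include_self = include_self

    def fit(self, X, y=None):
        _as_points(X)
        return self

    def transform(self, X):
        return deterministic_anonymize(X, self.k, self.include_self)
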