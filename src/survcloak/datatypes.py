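"""Core domain containers.

A :class:`SurvivalDataset` holds one right-censored time-to-event record per
subject (time, event flag, optional group label).  A :class:`SurvivalCurve`
is the raw product-limit output — distinct observed times with at-risk /
event / censoring counts and survival probabilities.  A
:class:`PrivacyCurve` is an anonymised release: plain (time, survival)
pairs plus method metadata, with censoring markers suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SurvivalRecord",
    "SurvivalDataset",
    "SurvivalCurve",
    "PrivacyCurve",
    "GuardPolicy",
    "GuardReport",
    "NoiseSpec",
    "GeneratorSpec",
    "CurveDelta",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator, optional group label.

    ``event`` is 1 when the event was observed and 0 when the subject was
    right-censored at ``time``.
    """

    time: float
    event: int
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be finite and >= 0, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event!r}")


class SurvivalDataset:
    """Ordered collection of subject records with a site/study label.

    Record order carries no meaning: every estimator in the package is
    permutation invariant.  Internally the data live in numpy arrays.
    """

    def __init__(
        self,
        times: Sequence[float],
        events: Sequence[int],
        groups: Optional[Sequence] = None,
        name: str = "dataset",
    ) -> None:
        times = np.asarray(times, dtype=float)
        events = np.asarray(events)
        if times.ndim != 1 or events.ndim != 1 or times.shape != events.shape:
            raise ValidationError("times and events must be 1-d and of equal length")
        if times.size and (not np.all(np.isfinite(times)) or np.any(times < 0)):
            raise ValidationError("all times must be finite and >= 0")
        if times.size and not np.all(np.isin(events, (0, 1))):
            raise ValidationError("all event indicators must be 0 or 1")
        self.times = times
        self.events = events.astype(np.int64)
        if groups is not None:
            groups = np.asarray(groups, dtype=object)
            if groups.shape != times.shape:
                raise ValidationError("groups must match times in length")
        self.groups = groups
        self.name = name

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[SurvivalRecord]:
        for i in range(len(self)):
            yield SurvivalRecord(
                float(self.times[i]),
                int(self.events[i]),
                None if self.groups is None else self.groups[i],
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurvivalDataset):
            return NotImplemented
        same_groups = (self.groups is None) == (other.groups is None) and (
            self.groups is None or np.array_equal(self.groups, other.groups)
        )
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.events, other.events)
            and same_groups
        )

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    # -- derived datasets ---------------------------------------------------
    def subset(self, indices: Sequence[int], name: Optional[str] = None) -> "SurvivalDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return SurvivalDataset(
            self.times[idx],
            self.events[idx],
            None if self.groups is None else self.groups[idx],
            name or self.name,
        )

    def drop_subject(self, index: int) -> "SurvivalDataset":
        """Dataset without the subject at ``index`` (the leave-one-out input)."""
        n = len(self)
        if not 0 <= index < n:
            raise ValidationError(f"subject index {index} out of range for n={n}")
        keep = np.delete(np.arange(n), index)
        return self.subset(keep, name=f"{self.name}[-{index}]")

    # -- conversions --------------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[SurvivalRecord], name: str = "dataset") -> "SurvivalDataset":
        groups = [r.group for r in records]
        has_groups = any(g is not None for g in groups)
        return cls(
            [r.time for r in records],
            [r.event for r in records],
            groups if has_groups else None,
            name,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "event": self.events})
        if self.groups is not None:
            df["group"] = self.groups
        return df

    def __repr__(self) -> str:
        return f"SurvivalDataset(name={self.name!r}, n={len(self)}, events={self.n_events})"


@dataclass
class SurvivalCurve:
    """Raw product-limit curve at the distinct observed times.

    Both event times and censoring-only times are listed, matching the
    grid a survival-fit object exposes (and that the smoother consumes).
    ``surv[i]`` is the estimate just after ``times[i]``; the recursion
    ``surv[i] = surv[i-1] * (1 - n_event[i] / n_risk[i])`` holds exactly,
    with ``surv[-1]`` read as 1.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    surv: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=np.int64)
        self.n_event = np.asarray(self.n_event, dtype=np.int64)
        self.n_censor = np.asarray(self.n_censor, dtype=np.int64)
        self.surv = np.asarray(self.surv, dtype=float)
        k = self.times.size
        if not (self.n_risk.size == self.n_event.size == self.n_censor.size == self.surv.size == k):
            raise ValidationError("curve fields must have equal length")
        if k == 0:
            raise ValidationError("curve must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("curve times must be strictly increasing")
        if np.any((self.surv < -1e-12) | (self.surv > 1 + 1e-12)):
            raise ValidationError("survival values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def event_times(self) -> np.ndarray:
        """Times at which at least one event occurred (the step locations)."""
        return self.times[self.n_event > 0]

    @property
    def censor_times(self) -> np.ndarray:
        return self.times[self.n_censor > 0]


@dataclass
class PrivacyCurve:
    """An anonymised survival curve as released to the analyst.

    Carries only (time, survival) pairs plus method metadata — no
    per-subject counts and no censoring markers.  ``method`` is one of
    ``loess``, ``probabilistic``, ``deterministic`` or ``none`` (raw
    passthrough, internal comparison only).
    """

    times: np.ndarray
    surv: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    site: str = "dataset"
    n_input: int = 0
    censor_marks_suppressed: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.size == 0:
            raise ValidationError("privacy curve must be non-empty")
        if self.times.shape != self.surv.shape:
            raise ValidationError("times and surv must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("privacy curve times must be non-decreasing")
        if np.any((self.surv < 0) | (self.surv > 1)):
            raise ValidationError("privacy curve survival values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of (time, survival) pairs."""
        return np.column_stack([self.times, self.surv])


@dataclass(frozen=True)
class GuardPolicy:
    """Server-side disclosure-control thresholds.

    Defaults follow common federated-analysis disclosure settings; they are
    conventions, not universal constants, and both are configurable.
    """

    min_subjects: int = 10
    min_events: int = 5

    def __post_init__(self) -> None:
        if self.min_subjects < 1 or self.min_events < 1:
            raise ValidationError("guard thresholds must be >= 1")


@dataclass(frozen=True)
class GuardReport:
    """Outcome of a disclosure-guard check.

    Names the rule(s) that fired; deliberately carries no data values.
    """

    passed: bool
    failed_rules: tuple
    policy: GuardPolicy
    site: str = "dataset"

    def __str__(self) -> str:
        if self.passed:
            return f"guard passed for site {self.site!r}"
        return f"guard failed for site {self.site!r}: {', '.join(self.failed_rules)}"


@dataclass(frozen=True)
class NoiseSpec:
    """Probabilistic-anonymisation noise: magnitude as a percentage of each
    perturbed value, the axes to perturb, and the seed."""

    percentage: float
    axes: tuple = ("x", "y")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.percentage < 0:
            raise ValidationError("noise percentage must be >= 0")
        axes = tuple(self.axes)
        if not axes or not set(axes) <= {"x", "y"}:
            raise ValidationError("axes must be a non-empty subset of {'x','y'}")
        object.__setattr__(self, "axes", axes)


@dataclass(frozen=True)
class GeneratorSpec:
    """Synthetic right-censored data recipe.

    ``event_dist`` is ``("weibull", shape, scale)`` or
    ``("exponential", rate)``; ``censor_dist`` is ``("uniform", lo, hi)``,
    ``("exponential", rate)`` or ``("none",)``.  ``groups`` optionally maps
    label -> per-group (n, event_dist) overrides.
    """

    n: int
    event_dist: tuple = ("weibull", 0.9, 140.0)
    censor_dist: tuple = ("uniform", 0.0, 2000.0)
    seed: int = 0
    groups: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        _check_dist(self.event_dist, ("weibull", "exponential"))
        _check_dist(self.censor_dist, ("uniform", "exponential", "none"))


def _check_dist(dist: tuple, allowed: tuple) -> None:
    if not dist or dist[0] not in allowed:
        raise ValidationError(f"distribution must be one of {allowed}, got {dist!r}")
    name, *params = dist
    expected = {"weibull": 2, "exponential": 1, "uniform": 2, "none": 0}[name]
    if len(params) != expected:
        raise ValidationError(f"{name} distribution takes {expected} parameter(s)")
    if name == "uniform":
        lo, hi = params
        if not 0 <= lo < hi:
            raise ValidationError("uniform censoring needs 0 <= lo < hi")
    elif any(p <= 0 for p in params):
        raise ValidationError("distribution parameters must be > 0")


@dataclass
class CurveDelta:
    """Distance between two released curves on a shared evaluation grid.

    ``sup_norm`` is the maximum absolute survival difference, ``l1`` the
    mean absolute difference (so ``l1 <= sup_norm``).  For smoothed curves
    the detected inflection times of each curve are included; for a
    leave-one-out comparison the withheld subject's time and event status
    are recorded.
    """

    sup_norm: float
    l1: float
    inflection_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    inflection_times_reduced: np.ndarray = field(default_factory=lambda: np.empty(0))
    removed_time: Optional[float] = None
    removed_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sup_norm < 0:
            raise ValidationError("sup_norm must be >= 0")
        if self.l1 > self.sup_norm + 1e-12:
            raise ValidationError("l1 cannot exceed sup_norm")
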