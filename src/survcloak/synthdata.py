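"""Synthetic right-censored survival data.

Latent event and censoring times are drawn independently per subject; the
record keeps time = min(E, C) and event = 1 iff E <= C (independent
censoring, the product-limit estimator's own assumption).  Weibull event
times with shape < 1 give the early-event skew characteristic of real
survival data — more events happen at earlier times.

``veteran_like_fixture`` emulates the size and gross shape of the classic
137-subject lung-cancer cohort (day-scale times, heavy early-event skew,
~7% censoring) with entirely synthetic values, so the rest of the package
is testable without any download.  ``load_veteran`` parses a user-supplied
export of the real dataset for optional checks; nothing is ever fetched.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import GeneratorSpec, SurvivalDataset
from .errors import ValidationError
from .io import read_records

__all__ = ["generate", "veteran_like_fixture", "load_veteran"]


def _draw(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = dist[0]
    if name == "weibull":
        shape, scale = dist[1], dist[2]
        return scale * rng.weibull(shape, n)
    if name == "exponential":
        return rng.exponential(1.0 / dist[1], n)
    if name == "uniform":
        return rng.uniform(dist[1], dist[2], n)
    if name == "none":
        return np.full(n, np.inf)
    raise ValidationError(f"unknown distribution {name!r}")


def generate(spec: GeneratorSpec) -> SurvivalDataset:
    """Draw a synthetic dataset according to ``spec``; deterministic under
    ``spec.seed``.

    With per-group overrides, groups are generated in sorted label order
    from a single seeded stream and concatenated, so the whole dataset is
    still reproducible from one seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.groups:
        times, events, labels = [], [], []
        for label in sorted(spec.groups):
            cfg = spec.groups[label]
            n_g = cfg.get("n", spec.n)
            event_dist = cfg.get("event_dist", spec.event_dist)
            e = _draw(event_dist, n_g, rng)
            c = _draw(spec.censor_dist, n_g, rng)
            times.append(np.minimum(e, c))
            events.append((e <= c).astype(np.int64))
            labels.extend([label] * n_g)
        return SurvivalDataset(np.concatenate(times), np.concatenate(events), labels, name=f"synthetic-seed{spec.seed}")
    e = _draw(spec.event_dist, spec.n, rng)
    c = _draw(spec.censor_dist, spec.n, rng)
    return SurvivalDataset(np.minimum(e, c), (e <= c).astype(np.int64), name=f"synthetic-seed{spec.seed}")


def veteran_like_fixture(seed: int = 2023) -> SurvivalDataset:
    """A 137-subject synthetic cohort shaped like the classic veteran
    lung-cancer data: Weibull(0.9, 140) event times (median below mean —
    early-event skew), uniform(0, 2000) censoring giving roughly 7%
    censored subjects, day-scale times.

    Values are synthetic; only the size and gross shape are emulated.
    """
    ds = generate(GeneratorSpec(n=137, event_dist=("weibull", 0.9, 140.0), censor_dist=("uniform", 0.0, 2000.0), seed=seed))
    ds.name = f"veteran-like-synthetic-seed{seed}"
    return ds


def load_veteran(path: str = "data/veteran.csv", event_coding: str = "01") -> Optional[SurvivalDataset]:
    """Parse a locally supplied export of the public veteran dataset
    (columns ``time`` and ``status``); returns None when the file is
    absent so optional real-data checks can skip cleanly.
    """
    try:
        return read_records(path, event_coding=event_coding, name="veteran")
    except FileNotFoundError:
        return None
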