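"""End-to-end privacy-enhancing curve generation.

This module plays the role of the server side in a federated deployment:
it validates a request against a disclosure policy, fits the product-limit
curve, applies the chosen anonymisation mechanism, strips censoring
markers, and returns only (time, survival) pairs plus method metadata.
``federated_curves`` applies the same contract independently per site —
one curve per site, never a pooled global curve, and no site's output
depends on another site's data.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .anonymize import deterministic_anonymize, monotone_repair, probabilistic_anonymize
from .datatypes import GuardPolicy, GuardReport, NoiseSpec, PrivacyCurve, SurvivalCurve, SurvivalDataset
from .errors import DisclosureControlError, ValidationError
from .km import fit_km, step_points
from .loess import LoessSmoother

__all__ = [
    "disclosure_guard",
    "privacy_enhanced_curve",
    "federated_curves",
    "render_curve",
    "METHODS",
]

METHODS = ("loess", "probabilistic", "deterministic", "none")


def disclosure_guard(data: SurvivalDataset, policy: GuardPolicy = GuardPolicy()) -> GuardReport:
    """Check a dataset against minimum-count disclosure rules.

    Failure is a report naming the rule(s) that fired, never an exception
    at this level, and never any data values.  Boundaries are inclusive:
    a dataset with exactly ``min_subjects`` subjects passes that rule.
    """
    failed = []
    if len(data) < policy.min_subjects:
        failed.append(f"min_subjects (threshold {policy.min_subjects})")
    if data.n_events < policy.min_events:
        failed.append(f"min_events (threshold {policy.min_events})")
    return GuardReport(passed=not failed, failed_rules=tuple(failed), policy=policy, site=data.name)


def _km_grid(curve: SurvivalCurve, anchor: bool) -> tuple:
    t = curve.times
    s = curve.surv
    if anchor and (t.size == 0 or t[0] > 0.0):
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return t, s


def privacy_enhanced_curve(
    data: SurvivalDataset,
    method: str = "loess",
    *,
    span="auto",
    degree: int = 1,
    noise_pct: float = 5.0,
    noise_axes: Sequence[str] = ("x", "y"),
    k: int = 5,
    seed: int = 0,
    anchor: bool = True,
    monotonise: bool = False,
    unsafe_raw: bool = False,
    policy: GuardPolicy = GuardPolicy(),
) -> PrivacyCurve:
    """Produce one privacy-enhanced survival curve for one dataset.

    The pipeline is: disclosure guard -> product-limit fit -> extract the
    (time, surv) grid at all distinct observed times (optionally anchored
    at (0, 1)) -> apply the mechanism -> clip survival to [0, 1] ->
    suppress censoring markers -> record method, parameters and seed.

    ``method='none'`` returns the raw staircase samples and is refused
    unless ``unsafe_raw=True``, mirroring the server-side posture that
    only privacy-enhanced results leave a site.  Smoothed output is NOT
    re-monotonised unless ``monotonise=True``: the smoother's raw output
    is the published behaviour; the projection is a utility option.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose one of {METHODS}")
    report = disclosure_guard(data, policy)
    if not report.passed:
        raise DisclosureControlError(str(report))
    if method == "none" and not unsafe_raw:
        raise ValidationError("method 'none' releases the raw curve; pass unsafe_raw=True to force it")

    curve = fit_km(data)
    t, s = _km_grid(curve, anchor)
    params: dict = {"anchor": anchor, "monotonise": monotonise}

    if method == "loess":
        smoother = LoessSmoother(span=span, degree=degree).fit(t, s)
        out_t, out_s = t, smoother.fitted_values_
        params.update(span=smoother.span_, degree=degree, aicc=smoother.aicc_, span_mode="auto" if span == "auto" else "fixed")
    elif method == "probabilistic":
        spec = NoiseSpec(noise_pct, tuple(noise_axes), seed)
        pts = probabilistic_anonymize(np.column_stack([t, s]), spec)
        out_t, out_s = pts[:, 0], pts[:, 1]
        params.update(noise_pct=noise_pct, noise_axes=tuple(noise_axes), seed=seed)
    elif method == "deterministic":
        pts = deterministic_anonymize(np.column_stack([t, s]), k)
        order = np.argsort(pts[:, 0], kind="stable")
        out_t, out_s = pts[order, 0], pts[order, 1]
        params.update(k=k)
    else:  # none
        out_t, out_s = t, s

    out_s = np.clip(out_s, 0.0, 1.0)
    if monotonise and method != "probabilistic":  # probabilistic repair already ran
        out_t, out_s = monotone_repair(out_t, out_s, repair_x=False)
    return PrivacyCurve(
        times=out_t,
        surv=out_s,
        method=method,
        params=params,
        site=data.name,
        n_input=len(data),
        censor_marks_suppressed=True,
    )


def federated_curves(
    sites: Sequence[SurvivalDataset],
    method: str = "loess",
    policy: GuardPolicy = GuardPolicy(),
    **options,
) -> dict:
    """Run the privacy pipeline independently on each site.

    Returns a mapping from site name to either a :class:`PrivacyCurve` or,
    for sites refused by the guard, the failing :class:`GuardReport` — a
    refusal at one site never blocks the others.  Each site's output is a
    pure function of that site's own data.
    """
    sites = list(sites)
    if not sites:
        raise ValidationError("need at least one site")
    results: dict = {}
    for site in sites:
        report = disclosure_guard(site, policy)
        if not report.passed:
            results[site.name] = report
        else:
            results[site.name] = privacy_enhanced_curve(site, method, policy=policy, **options)
    return results


def render_curve(
    curves: Union[PrivacyCurve, Sequence[PrivacyCurve]],
    path: str,
    raw_overlay: Optional[SurvivalCurve] = None,
    format: Optional[str] = None,
    overlay_censor_marks: bool = False,
) -> None:
    """Render privacy curves (smooth polylines) with an optional raw
    staircase overlay, SVG or PNG.

    Privacy curves are never drawn with censoring tick marks.  Marks can
    be requested for the raw overlay only (e.g. for internal before/after
    comparisons); they are drawn in a group with gid ``censor-marks`` so
    their presence is auditable in SVG output.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(curves, PrivacyCurve):
        curves = [curves]
    curves = list(curves)
    if not curves:
        raise ValidationError("need at least one curve to render")
    if format is None:
        format = "png" if path.lower().endswith(".png") else "svg"

    fig, ax = plt.subplots(figsize=(7, 4.5))
    if raw_overlay is not None:
        verts, marks = step_points(raw_overlay, include_censor_marks=overlay_censor_marks)
        ax.plot(verts[:, 0], verts[:, 1], color="black", lw=1.2, label="raw (unmodified)")
        if overlay_censor_marks and marks.size:
            ax.scatter(marks[:, 0], marks[:, 1], marker="+", color="black", gid="censor-marks", zorder=3)
    for pc in curves:
        label = f"{pc.site} ({pc.method})"
        if pc.method == "none":
            ax.step(pc.times, pc.surv, where="post", label=label)
        else:
            ax.plot(pc.times, pc.surv, label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    try:
        fig.savefig(path, format=format)
    finally:
        plt.close(fig)
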