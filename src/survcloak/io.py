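"""Readers and writers for subject tables and curve outputs.

Subject data come from delimited text (CSV/TSV, UTF-8, header row
required) with default columns ``time`` and ``event`` (alias ``status``)
plus an optional ``group``.  Curves are written as two-column TSV or as
JSON carrying method metadata; both round-trip to full float precision.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import PrivacyCurve, SurvivalCurve, SurvivalDataset
from .errors import ConfigurationError, ParseError, ValidationError

__all__ = ["read_records", "write_curve", "read_curve"]

_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


def _resolve_delimiter(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".tab") else ","


def _find_column(df: pd.DataFrame, logical: str, column_map: Mapping[str, str], aliases: tuple = ()) -> Optional[str]:
    if logical in column_map:
        name = column_map[logical]
        if name not in df.columns:
            raise ConfigurationError(f"mapped column {name!r} for {logical!r} not found in header {list(df.columns)}")
        return name
    for name in (logical, *aliases):
        if name in df.columns:
            return name
    return None


def _parse_event(raw, row: int, event_coding: str) -> int:
    text = str(raw).strip().lower()
    if event_coding == "12":
        if text in ("1", "2"):
            return int(text) - 1
        raise ParseError(f"row {row}: event value {raw!r} not in 1/2 coding")
    if text in _TRUTHY:
        return 1
    if text in _FALSY:
        return 0
    raise ParseError(f"row {row}: cannot parse event value {raw!r} as 0/1")


def read_records(
    path: str,
    delimiter: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
    event_coding: str = "01",
    name: Optional[str] = None,
) -> SurvivalDataset:
    """Read a subject table into a :class:`SurvivalDataset`.

    Parameters
    ----------
    path : str
        CSV or TSV file with a header row.  The delimiter is inferred from
        the extension unless given explicitly.
    column_map : mapping, optional
        Maps logical names (``time``, ``event``, ``group``) to actual
        column headers, e.g. ``{"event": "cens"}``.
    event_coding : {"01", "12"}
        ``"12"`` recodes the 1 = censored / 2 = event convention used by
        some survival datasets.  The default accepts 0/1 and TRUE/FALSE.

    Rows with missing time or event are rejected with a :class:`ParseError`
    naming the 1-based data row — never silently dropped.
    """
    if event_coding not in ("01", "12"):
        raise ConfigurationError(f"event_coding must be '01' or '12', got {event_coding!r}")
    column_map = dict(column_map or {})
    sep = _resolve_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8", skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"cannot parse {path!r}: {exc}") from exc

    time_col = _find_column(df, "time", column_map)
    event_col = _find_column(df, "event", column_map, aliases=("status",))
    group_col = _find_column(df, "group", column_map)
    if time_col is None:
        raise ConfigurationError(f"required column 'time' not found in header {list(df.columns)}")
    if event_col is None:
        raise ConfigurationError(f"required column 'event' (alias 'status') not found in header {list(df.columns)}")

    times, events = [], []
    for i, (raw_t, raw_e) in enumerate(zip(df[time_col], df[event_col]), start=1):
        if pd.isna(raw_t) or str(raw_t).strip() == "":
            raise ParseError(f"row {i}: missing time value")
        if pd.isna(raw_e) or str(raw_e).strip() == "":
            raise ParseError(f"row {i}: missing event value")
        try:
            t = float(str(raw_t).strip())
        except ValueError as exc:
            raise ParseError(f"row {i}: cannot parse time value {raw_t!r}") from exc
        if not np.isfinite(t) or t < 0:
            raise ValidationError(f"row {i}: time must be finite and >= 0, got {t}")
        times.append(t)
        events.append(_parse_event(raw_e, i, event_coding))

    groups = None
    if group_col is not None:
        groups = [None if pd.isna(g) else str(g) for g in df[group_col]]
    return SurvivalDataset(times, events, groups, name or os.path.splitext(os.path.basename(path))[0])


def _curve_payload(curve: Union[SurvivalCurve, PrivacyCurve]) -> dict:
    if isinstance(curve, PrivacyCurve):
        return {
            "method": curve.method,
            "params": curve.params,
            "site": curve.site,
            "n_input": curve.n_input,
            "censor_marks_suppressed": curve.censor_marks_suppressed,
            "points": [[float(t), float(s)] for t, s in zip(curve.times, curve.surv)],
        }
    return {
        "method": "raw_km",
        "params": {"n_total": int(curve.n_total)},
        "points": [[float(t), float(s)] for t, s in zip(curve.times, curve.surv)],
    }


def write_curve(curve: Union[SurvivalCurve, PrivacyCurve], path: str, format: str = "tsv") -> None:
    """Write a curve as TSV (``time<TAB>surv``) or JSON with metadata.

    Floats are serialised with ``repr`` so a read-back reproduces every
    time and survival value exactly.
    """
    if len(curve) == 0:
        raise ValidationError("cannot write an empty curve")
    if format == "tsv":
        lines = ["time\tsurv"]
        lines += [f"{float(t)!r}\t{float(s)!r}" for t, s in zip(curve.times, curve.surv)]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_curve_payload(curve), fh, indent=2)
            fh.write("\n")
    else:
        raise ConfigurationError(f"unknown curve format {format!r} (use 'tsv' or 'json')")


def read_curve(path: str, format: Optional[str] = None) -> PrivacyCurve:
    """Read back a curve written by :func:`write_curve`.

    TSV input yields a curve with method ``"none"`` (the file carries no
    metadata); JSON restores the stored method and parameters.
    """
    if format is None:
        format = "json" if path.lower().endswith(".json") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if list(df.columns) != ["time", "surv"]:
            raise ParseError(f"expected columns ['time', 'surv'], got {list(df.columns)}")
        return PrivacyCurve(df["time"].to_numpy(float), df["surv"].to_numpy(float), method="none")
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    pts = np.asarray(payload["points"], dtype=float).reshape(-1, 2)
    return PrivacyCurve(
        pts[:, 0],
        pts[:, 1],
        method=payload.get("method", "none"),
        params=payload.get("params", {}),
        site=payload.get("site", "dataset"),
        n_input=payload.get("n_input", 0),
        censor_marks_suppressed=payload.get("censor_marks_suppressed", True),
    )
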