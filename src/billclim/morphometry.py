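"""Bill surface area and specimen inclusion filters.

Bill surface area (SA, mm²) is the heat-exchange surface of the bill,
approximated from the three linear caliper measurements — exposed culmen
length *l*, bill width *w* and bill depth *d* at the anterior edge of the
nostrils — by the lateral surface of a right circular cone.  The cone
radius averages the semi-width and semi-depth, r = (w + d) / 4, and the
slant height is s = sqrt(r² + l²), giving SA = π·r·s.  The exact cone
approximation is a pluggable component (``formula=`` argument) because
several variants circulate in the bill-morphology literature; everything
downstream only requires SA to be a smooth, monotone composite of
(l, w, d).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "bill_surface_area",
    "cone_lateral_area",
    "FilterRules",
    "filter_specimens",
]

#: Columns that must be present and non-missing for a record to be analysable.
REQUIRED_NUMERIC = ("bill_length_mm", "bill_width_mm", "bill_depth_mm", "tarsus_mm")
REQUIRED_COORDS = ("decimal_latitude", "decimal_longitude")


def cone_lateral_area(l, w, d):
    """Lateral surface of a right circular cone with r = (w+d)/4, s = sqrt(r²+l²)."""
    l = np.asarray(l, dtype=float)
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    r = (w + d) / 4.0
    s = np.sqrt(r * r + l * l)
    return np.pi * r * s


def bill_surface_area(l, w, d, formula=cone_lateral_area):
    """Bill surface area in mm² from bill length, width and depth (mm).

    Parameters
    ----------
    l, w, d : float or array-like
        Bill length, width and depth in mm; all must be strictly positive.
    formula : callable, optional
        ``formula(l, w, d) -> SA``.  Defaults to the circular-cone lateral
        surface; swap in an alternative (e.g. elliptical-cone quadrature)
        without touching callers.

    Returns
    -------
    float or ndarray
        Surface area, mm².  Scalar inputs give a Python float.
    """
    arr_l, arr_w, arr_d = (np.asarray(x, dtype=float) for x in (l, w, d))
    if np.any(arr_l <= 0) or np.any(arr_w <= 0) or np.any(arr_d <= 0):
        raise ValueError("bill dimensions must be strictly positive")
    sa = formula(arr_l, arr_w, arr_d)
    if np.ndim(l) == 0 and np.ndim(w) == 0 and np.ndim(d) == 0:
        return float(sa)
    return sa


@dataclass(frozen=True)
class FilterRules:
    """Inclusion rules for specimen records.

    The seasonal window and year range are inclusive on both ends
    ("between 15 March and 30 September", "from 1900 to 1950" read
    inclusively).  The window is defined by (month, day) pairs so it
    applies to every year in the range.
    """

    season_start: tuple[int, int] = (3, 15)  # (month, day)
    season_end: tuple[int, int] = (9, 30)
    year_min: int = 1900
    year_max: int = 1950
    subspecies: frozenset[str] = frozenset({"pinosus", "thurberi"})
    sexes: frozenset[str] = frozenset({"male", "female"})


def _check_record(row: pd.Series, rules: FilterRules) -> tuple[str, str] | None:
    """Return (reason_code, detail) for a rejected record, or None if kept."""
    try:
        d = pd.Timestamp(row["event_date"])
        if pd.isna(d):
            raise ValueError
    except (ValueError, TypeError):
        return "unparsable_date", f"event_date={row['event_date']!r}"
    if not (rules.year_min <= d.year <= rules.year_max):
        return "outside_year_range", f"year={d.year}"
    start = date(d.year, *rules.season_start)
    end = date(d.year, *rules.season_end)
    if not (start <= d.date() <= end):
        return "outside_season", f"date={d.date().isoformat()}"
    ssp = row.get("subspecies")
    if not isinstance(ssp, str) or ssp not in rules.subspecies:
        return "unknown_subspecies", f"subspecies={ssp!r}"
    sex = row.get("sex")
    if not isinstance(sex, str) or sex not in rules.sexes:
        return "missing_or_unknown_sex", f"sex={sex!r}"
    for col in REQUIRED_COORDS:
        v = row.get(col)
        if v is None or (isinstance(v, float) and not np.isfinite(v)) or pd.isna(v):
            return "missing_coordinates", f"{col} missing"
    for col in REQUIRED_NUMERIC:
        v = row.get(col)
        if v is None or pd.isna(v):
            return "missing_measurement", f"{col} missing"
        if float(v) <= 0:
            return "nonpositive_measurement", f"{col}={v}"
    return None


def filter_specimens(
    table: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion filters; never raises on a bad record.

    Returns ``(kept, rejects)``.  ``kept`` is a copy of the passing rows
    with ``year`` and ``month`` refreshed from the parsed event date.
    ``rejects`` has columns ``key, reason_code, detail`` — one row per
    dropped record, first failing rule wins.  Filtering is idempotent.
    """
    rules = rules or FilterRules()
    keep_idx: list = []
    rej_rows: list[dict] = []
    for idx, row in table.iterrows():
        verdict = _check_record(row, rules)
        if verdict is None:
            keep_idx.append(idx)
        else:
            code, detail = verdict
            rej_rows.append(
                {"key": row.get("catalog_id", idx), "reason_code": code, "detail": detail}
            )
    kept = table.loc[keep_idx].copy()
    if len(kept):
        dates = pd.to_datetime(kept["event_date"])
        kept["year"] = dates.dt.year.to_numpy()
        kept["month"] = dates.dt.month.to_numpy()
    rejects = pd.DataFrame(rej_rows, columns=["key", "reason_code", "detail"])
    return kept, rejects
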