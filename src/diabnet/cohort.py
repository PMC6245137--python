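"""Cohort construction: index dates, complication detection, fast/slow
progressor labeling, and the second-year feature window.

Day 0 is the index date — the first day any type-2-diabetes inclusion
criterion is met (a T2DM diagnosis code, an HbA1C result >= 6.5%, or an
externally supplied anti-diabetes medication day). Features feeding the
network come only from the second year after the index (days 366-730): the
first year is skipped to avoid diagnoses made in the acute situation around
the index itself, and later years are skipped because attrition biases long
follow-up toward healthier patients.

A patient is a *fast* progressor when the time from index to first
complication lies in the fastest quartile of eligible patients, *slow* when
it lies in the slowest quartile; patients whose complication precedes the
index or occurs within one year of it are excluded outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import (
    HBA1C_THRESHOLD,
    T2DM_CODES,
    complication_prefixes,
    matches_any,
)

__all__ = [
    "WINDOW",
    "ProgressorLabel",
    "find_index_day",
    "detect_complication",
    "detect_complication_days",
    "label_progressors",
    "window_features",
]

#: Feature window (lo, hi]: day offsets kept for feature extraction.
WINDOW: tuple[int, int] = (365, 730)


@dataclass(frozen=True)
class ProgressorLabel:
    study_id: object
    complication: str
    days_to_complication: int
    label: str  # "fast" | "slow" | "excluded"


def find_index_day(
    events: Iterable[tuple[int, str]] = (),
    labs: Iterable[tuple[int, str, float]] = (),
    med_flag_days: Sequence[int] = (),
    hba1c_variable: str = "hba1c",
) -> int | None:
    """Earliest day any inclusion criterion holds for one patient.

    Criteria: a diagnosis code prefix-matching the T2DM list, an HbA1C lab
    value >= 6.5, or a day on the externally supplied medication-flag list.
    Days are offsets against whatever provisional origin the caller uses;
    re-zeroing so the returned day becomes 0 is the caller's responsibility.
    Returns None when no criterion is ever met.
    """
    candidates: list[int] = []
    for day, code in events:
        if matches_any(code, T2DM_CODES):
            candidates.append(int(day))
    for day, variable, value in labs:
        if variable == hba1c_variable and value is not None and float(value) >= HBA1C_THRESHOLD:
            candidates.append(int(day))
    candidates.extend(int(d) for d in med_flag_days)
    return min(candidates) if candidates else None


def detect_complication(
    events: Iterable[tuple[int, str]], complication: str
) -> int | None:
    """First day a code prefix-matching the complication's list appears.

    Matching is done on the full, untruncated code so that e.g. the
    retinopathy list entry "362" does not have to disambiguate itself from
    the 362.0x diabetes inclusion codes by other means.
    """
    prefixes = complication_prefixes(complication)
    days = [int(day) for day, code in events if matches_any(code, prefixes)]
    return min(days) if days else None


def detect_complication_days(
    diagnosis: pd.DataFrame, complication: str
) -> dict:
    """Vectorised :func:`detect_complication` over a diagnosis table.

    Returns ``{study_id: first matching day}`` for patients with at least one
    matching event.
    """
    prefixes = complication_prefixes(complication)
    codes = diagnosis["DX_CODE"].astype(str).str.strip().str.upper()
    mask = np.zeros(len(diagnosis), dtype=bool)
    for p in prefixes:
        mask |= codes.str.startswith(p).to_numpy()
    hits = diagnosis.loc[mask]
    return hits.groupby("STUDYID")["DX_INDEX"].min().astype(int).to_dict()


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest value."""
    n = len(sorted_vals)
    idx = max(math.ceil(q * n), 1) - 1
    return float(sorted_vals[min(idx, n - 1)])


def label_progressors(
    days_to_complication: Mapping,
    complication: str = "kidney",
    q_fast: float = 0.25,
    q_slow: float = 0.75,
    min_days: int = 365,
    fast_day_cap: int | None = None,
) -> pd.DataFrame:
    """Assign fast/slow/excluded labels from times to first complication.

    Patients whose complication occurred on or before ``min_days`` (or before
    the index) are excluded before the quantiles are computed. Among the
    rest, times at or below the ``q_fast`` nearest-rank quantile are fast and
    times at or above the ``q_slow`` quantile are slow; everyone in between
    is excluded, keeping the two groups disjoint. A patient who would qualify
    for both groups at once (possible only when the two quantile values
    coincide, e.g. all times identical) is excluded — ties resolve toward
    exclusion. ``fast_day_cap`` optionally additionally requires fast
    progressors' complication day to be <= the cap (off by default).

    Returns a DataFrame with columns STUDYID, COMPLICATION,
    DAYS_TO_COMPLICATION, LABEL.
    """
    items = sorted(days_to_complication.items(), key=lambda kv: str(kv[0]))
    if not items:
        return pd.DataFrame(
            columns=["STUDYID", "COMPLICATION", "DAYS_TO_COMPLICATION", "LABEL"]
        )
    ids = [k for k, _ in items]
    days = np.array([int(v) for _, v in items])
    eligible = days > min_days
    labels = np.full(len(days), "excluded", dtype=object)
    if eligible.sum() > 0:
        elig_days = np.sort(days[eligible])
        cut_fast = _nearest_rank(elig_days, q_fast)
        cut_slow = _nearest_rank(elig_days, q_slow)
        is_fast = eligible & (days <= cut_fast)
        is_slow = eligible & (days >= cut_slow)
        both = is_fast & is_slow
        labels[is_fast & ~both] = "fast"
        labels[is_slow & ~both] = "slow"
        if fast_day_cap is not None:
            labels[(labels == "fast") & (days > fast_day_cap)] = "excluded"
    return pd.DataFrame({
        "STUDYID": ids,
        "COMPLICATION": complication,
        "DAYS_TO_COMPLICATION": days,
        "LABEL": labels,
    })


def window_features(
    events: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    complication: str | None = None,
    window: tuple[int, int] = WINDOW,
):
    """Restrict events and labs to the feature window and strip leakage.

    Keeps facts with ``window[0] < day <= window[1]`` (day offsets relative
    to the index). When ``complication`` is given, events whose code
    prefix-matches that complication's list are additionally removed so the
    outcome definition can never leak into the features.

    Returns ``(events', labs')``; ``labs'`` is None when ``labs`` is None.
    """
    lo, hi = window
    day = events["DX_INDEX"].astype(int)
    keep = (day > lo) & (day <= hi)
    if complication is not None:
        prefixes = complication_prefixes(complication)
        codes = events["DX_CODE"].astype(str).str.strip().str.upper()
        is_outcome = np.zeros(len(events), dtype=bool)
        for p in prefixes:
            is_outcome |= codes.str.startswith(p).to_numpy()
        keep &= ~is_outcome
    events_w = events.loc[keep].reset_index(drop=True)

    labs_w = None
    if labs is not None:
        lday = labs["DAYS_VIS_INDEX"].astype(int)
        labs_w = labs.loc[(lday > lo) & (lday <= hi)].reset_index(drop=True)
    return events_w, labs_w
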