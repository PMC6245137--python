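"""Feature extraction: typed tokens, lab QC, quartiling, and cohort filters.

Every piece of windowed patient information becomes a :class:`FeatureToken`,
the typed node of the heterogeneous network:

- ``diagnosis`` tokens: ICD categories, i.e. codes truncated to their first
  three characters (subtypes collapse onto the primary diagnosis);
- ``demographic`` tokens: gender, race (verbatim), and the patient's age
  quartile;
- ``clinical_quartile`` tokens: a lab variable's per-patient summary mapped
  to the quartile of the training distribution;
- ``clinical_status`` tokens: variables dichotomised to normal/abnormal by a
  configurable threshold table.

Cleaning follows the source protocol: lab values outside configured
physiologic bounds or more than 2 SD from the per-variable median are
dropped; tokens carried by fewer than 1% of patients are removed; patients
with fewer than 5 or more than twice the median number of in-window
diagnoses are removed; and the fast/slow classes are downsampled to equal
size before network construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureToken",
    "QuartileBoundaries",
    "StatusRule",
    "DEFAULT_STATUS_RULES",
    "truncate_icd",
    "qc_lab_values",
    "fit_quartiles",
    "quartile_level",
    "tokenize_patient",
    "tokenize_cohort",
    "prevalence_filter",
    "patient_filters",
    "balance_classes",
]


@dataclass(frozen=True, order=True)
class FeatureToken:
    """A typed network node; identity (and ordering) is (kind, name, level)."""

    kind: str   # diagnosis | demographic | clinical_quartile | clinical_status
    name: str   # ICD category, demographic field, or lab variable
    level: str  # category value, quartile "0".."3", or "normal"/"abnormal"

    def __str__(self) -> str:  # e.g. "clinical_quartile:egfr=0"
        return f"{self.kind}:{self.name}={self.level}"


@dataclass(frozen=True)
class QuartileBoundaries:
    """Nearest-rank 25/50/75th percentile cuts of a training distribution."""

    variable: str
    cuts: tuple[float, float, float]

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cuts
        if not (c1 <= c2 <= c3):
            raise ValueError(f"{self.variable}: quartile cuts must be non-decreasing")


@dataclass(frozen=True)
class StatusRule:
    """Dichotomises a clinical variable into normal/abnormal.

    ``op`` is "ge" (abnormal when value >= threshold) or "le" (abnormal when
    value <= threshold).
    """

    variable: str
    threshold: float
    op: str = "ge"

    def status(self, value: float) -> str:
        abnormal = value >= self.threshold if self.op == "ge" else value <= self.threshold
        return "abnormal" if abnormal else "normal"


# Conventional clinical cut-offs used as implementation defaults for the
# pre-processed status variables; they are not calibrated values.
DEFAULT_STATUS_RULES: dict[str, StatusRule] = {
    "systolic_bp": StatusRule("systolic_bp", 140.0, "ge"),        # hypertension
    "glucose_fasting": StatusRule("glucose_fasting", 126.0, "ge"),  # hyperglycemia
    "triglycerides": StatusRule("triglycerides", 150.0, "ge"),
    "creatinine": StatusRule("creatinine", 1.3, "ge"),            # high serum creatinine
    "ldl_c": StatusRule("ldl_c", 160.0, "ge"),
    "hdl_c": StatusRule("hdl_c", 40.0, "le"),                     # low HDL abnormal
    "bmi": StatusRule("bmi", 30.0, "ge"),                         # weight classification
}


def truncate_icd(code: str) -> str:
    """ICD category: the part before the first ".", capped at 3 characters."""
    if not isinstance(code, str) or not code.strip():
        raise ValueError(f"cannot truncate malformed diagnosis code {code!r}")
    return code.strip().upper().split(".", 1)[0][:3]


def qc_lab_values(
    labs: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    value_col: str = "value",
    variable_col: str = "variable",
) -> pd.DataFrame:
    """Quality-control lab values in long format (one row per measurement).

    Two passes per variable: values outside the configured [min, max] bounds
    are dropped first; then values farther than 2 sample SD from the median
    of the surviving values are dropped. Variables without bounds pass the
    range check trivially; a zero SD (e.g. all values identical) drops
    nothing in the second pass.
    """
    bounds = bounds or {}
    keep = np.ones(len(labs), dtype=bool)
    values = labs[value_col].astype(float).to_numpy()
    variables = labs[variable_col].astype(str).to_numpy()
    for var in pd.unique(variables):
        m = variables == var
        v = values[m]
        in_range = np.isfinite(v)
        if var in bounds:
            lo, hi = bounds[var]
            in_range &= (v >= lo) & (v <= hi)
        passed = v[in_range]
        if len(passed) > 0:
            med = float(np.median(passed))
            sd = float(np.std(passed, ddof=1)) if len(passed) > 1 else 0.0
            ok = in_range.copy()
            if sd > 0:
                ok &= np.abs(v - med) <= 2.0 * sd
        else:
            ok = in_range
        keep[m] = ok
    return labs.loc[keep].reset_index(drop=True)


def qc_clinical_table(
    clinical: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """:func:`qc_lab_values` applied to the wide clinical table.

    Failing measurements become missing cells (NaN) rather than dropped rows,
    preserving the one-row-per-visit layout.
    """
    bounds = bounds or {}
    base = {"STUDYID", "AGE", "DAYS_VIS_INDEX", "INDEX_AGE"}
    out = clinical.copy()
    for var in [c for c in clinical.columns if c not in base]:
        v = out[var].astype(float).to_numpy()
        in_range = np.isfinite(v)
        if var in bounds:
            lo, hi = bounds[var]
            in_range &= (v >= lo) & (v <= hi)
        passed = v[in_range]
        ok = in_range.copy()
        if len(passed) > 1:
            med = float(np.median(passed))
            sd = float(np.std(passed, ddof=1))
            if sd > 0:
                ok &= np.abs(v - med) <= 2.0 * sd
        out[var] = np.where(ok, v, np.nan)
    return out


def fit_quartiles(values: Iterable[float], variable: str = "") -> QuartileBoundaries:
    """Nearest-rank 25/50/75th percentiles of a training sample (>= 4 values)."""
    v = np.sort(np.asarray([x for x in values if np.isfinite(x)], dtype=float))
    if len(v) < 4:
        raise ValueError(
            f"fit_quartiles({variable!r}): need >= 4 finite values, got {len(v)}"
        )
    n = len(v)
    cuts = tuple(float(v[max(math.ceil(q * n), 1) - 1]) for q in (0.25, 0.50, 0.75))
    return QuartileBoundaries(variable, cuts)  # type: ignore[arg-type]


def quartile_level(value: float, boundaries: QuartileBoundaries) -> int:
    """Quartile index 0-3; ties go down (value == cut maps to the lower bin)."""
    return int(np.searchsorted(np.asarray(boundaries.cuts), value, side="left"))


def _lab_summary(values: np.ndarray, how: str) -> float:
    if how == "mean":
        return float(np.mean(values))
    if how == "last":
        return float(values[-1])
    if how == "min":
        return float(np.min(values))
    if how == "max":
        return float(np.max(values))
    raise ValueError(f"unknown lab summary {how!r}")


def tokenize_patient(
    record: Mapping,
    events: Iterable[tuple[int, str]],
    labs: Iterable[tuple[int, str, float]],
    boundaries: Mapping[str, QuartileBoundaries],
    status_rules: Mapping[str, StatusRule] | None = None,
    lab_summary: str = "mean",
) -> frozenset[FeatureToken]:
    """Token set of one patient from windowed, QC-passed facts.

    ``record`` supplies GENDER, RACE and INDEX_AGE; ``boundaries`` must be
    fitted on training patients only and include an "age" entry for the age
    quartile. Tokens are a set: repeated diagnoses in the same category
    collapse, and each lab variable contributes one token from the summary
    (default: mean) of its in-window values.
    """
    status_rules = DEFAULT_STATUS_RULES if status_rules is None else status_rules
    tokens: set[FeatureToken] = set()

    gender = record.get("GENDER")
    if gender is not None and not pd.isna(gender):
        tokens.add(FeatureToken("demographic", "gender", str(gender)))
    race = record.get("RACE")
    if race is not None and not pd.isna(race):
        tokens.add(FeatureToken("demographic", "race", str(race)))
    age = record.get("INDEX_AGE")
    if age is not None and not pd.isna(age) and "age" in boundaries:
        level = quartile_level(float(age), boundaries["age"])
        tokens.add(FeatureToken("demographic", "age_quartile", str(level)))

    for _day, code in events:
        tokens.add(FeatureToken("diagnosis", truncate_icd(code), "present"))

    by_var: dict[str, list[float]] = {}
    for _day, variable, value in labs:
        if value is None or not np.isfinite(value):
            continue
        by_var.setdefault(str(variable), []).append(float(value))
    for variable, vals in by_var.items():
        summary = _lab_summary(np.asarray(vals), lab_summary)
        rule = status_rules.get(variable)
        if rule is not None:
            tokens.add(FeatureToken("clinical_status", variable, rule.status(summary)))
        elif variable in boundaries:
            level = quartile_level(summary, boundaries[variable])
            tokens.add(FeatureToken("clinical_quartile", variable, str(level)))
    return frozenset(tokens)


def tokenize_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    clinical: pd.DataFrame | None,
    boundaries: Mapping[str, QuartileBoundaries],
    status_rules: Mapping[str, StatusRule] | None = None,
    lab_summary: str = "mean",
) -> dict:
    """Token sets for every patient in ``patients`` (vectorised).

    ``events`` must already be windowed; ``clinical`` is the wide lab table
    (one column per variable), already windowed and QC-passed. Produces the
    same sets as calling :func:`tokenize_patient` per patient.
    """
    status_rules = DEFAULT_STATUS_RULES if status_rules is None else status_rules
    ids = patients["STUDYID"].tolist()
    token_sets: dict = {sid: set() for sid in ids}

    for _, row in patients.iterrows():
        sid = row["STUDYID"]
        if not pd.isna(row.get("GENDER")):
            token_sets[sid].add(FeatureToken("demographic", "gender", str(row["GENDER"])))
        if not pd.isna(row.get("RACE")):
            token_sets[sid].add(FeatureToken("demographic", "race", str(row["RACE"])))
        if "age" in boundaries and not pd.isna(row.get("INDEX_AGE")):
            lvl = quartile_level(float(row["INDEX_AGE"]), boundaries["age"])
            token_sets[sid].add(FeatureToken("demographic", "age_quartile", str(lvl)))

    if len(events):
        ev = events[events["STUDYID"].isin(token_sets)]
        cats = ev["DX_CODE"].astype(str).str.strip().str.upper()
        cats = cats.str.split(".", n=1).str[0].str[:3]
        for sid, cat in zip(ev["STUDYID"], cats):
            token_sets[sid].add(FeatureToken("diagnosis", cat, "present"))

    if clinical is not None and len(clinical):
        base = {"STUDYID", "AGE", "DAYS_VIS_INDEX", "INDEX_AGE"}
        lab_vars = [c for c in clinical.columns if c not in base]
        cl = clinical[clinical["STUDYID"].isin(token_sets)]
        for variable in lab_vars:
            col = cl[["STUDYID", variable]].dropna()
            if not len(col):
                continue
            grouped = col.groupby("STUDYID")[variable]
            if lab_summary == "mean":
                summary = grouped.mean()
            elif lab_summary == "last":
                summary = grouped.last()
            elif lab_summary == "min":
                summary = grouped.min()
            elif lab_summary == "max":
                summary = grouped.max()
            else:
                raise ValueError(f"unknown lab summary {lab_summary!r}")
            rule = status_rules.get(variable)
            if rule is not None:
                for sid, val in summary.items():
                    token_sets[sid].add(
                        FeatureToken("clinical_status", variable, rule.status(float(val)))
                    )
            elif variable in boundaries:
                cuts = np.asarray(boundaries[variable].cuts)
                levels = np.searchsorted(cuts, summary.to_numpy(dtype=float), side="left")
                for sid, lvl in zip(summary.index, levels):
                    token_sets[sid].add(
                        FeatureToken("clinical_quartile", variable, str(int(lvl)))
                    )

    return {sid: frozenset(s) for sid, s in token_sets.items()}


def prevalence_filter(
    token_sets: Mapping, min_frac: float = 0.01
) -> set[FeatureToken]:
    """Tokens carried by at least ``ceil(min_frac * N)`` of the N patients."""
    if not token_sets:
        raise ValueError("prevalence_filter: empty cohort")
    n = len(token_sets)
    need = math.ceil(min_frac * n)
    counts: dict[FeatureToken, int] = {}
    for s in token_sets.values():
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    return {t for t, c in counts.items() if c >= need}


def patient_filters(
    diagnosis_counts: Mapping,
    min_count: int = 5,
    cap_multiplier: float = 2.0,
    median_count: float | None = None,
) -> tuple[list, float]:
    """Patients with >= ``min_count`` and <= ``cap_multiplier`` x median diagnoses.

    The median is computed over the supplied counts before any removal (or
    taken from ``median_count`` when the threshold was fitted elsewhere, e.g.
    on a training split). Returns ``(retained ids, median used)``.
    """
    if not diagnosis_counts:
        return [], float("nan")
    counts = {k: int(v) for k, v in diagnosis_counts.items()}
    med = float(np.median(list(counts.values()))) if median_count is None else float(median_count)
    cap = cap_multiplier * med
    kept = [k for k, c in sorted(counts.items(), key=lambda kv: str(kv[0]))
            if min_count <= c <= cap]
    return kept, med


def balance_classes(fast_ids: Sequence, slow_ids: Sequence, seed: int = 0):
    """Downsample the larger class to the smaller's size, without replacement."""
    if len(fast_ids) == 0 or len(slow_ids) == 0:
        raise ValueError("balance_classes: both classes must be nonempty")
    rng = np.random.default_rng(seed)
    fast = sorted(fast_ids, key=str)
    slow = sorted(slow_ids, key=str)
    m = min(len(fast), len(slow))
    if len(fast) > m:
        fast = [fast[i] for i in sorted(rng.choice(len(fast), size=m, replace=False))]
    if len(slow) > m:
        slow = [slow[i] for i in sorted(rng.choice(len(slow), size=m, replace=False))]
    return fast, slow
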