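"""Tokenization, lab QC, quartiles, and the cohort cleaning filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import diabnet as dn
from diabnet.features import (
    DEFAULT_STATUS_RULES,
    FeatureToken,
    QuartileBoundaries,
    qc_clinical_table,
)


# --- truncate_icd -----------------------------------------------------------

@pytest.mark.parametrize("code,expected", [
    ("250.01", "250"),
    ("I50.22", "I50"),
    ("K40", "K40"),
    ("i50.22", "I50"),
    ("362.01", "362"),
    (" E11.9 ", "E11"),
])
def test_truncate_icd(code, expected):
    assert dn.truncate_icd(code) == expected


def test_truncate_empty_raises():
    with pytest.raises(ValueError):
        dn.truncate_icd("")
    with pytest.raises(ValueError):
        dn.truncate_icd("   ")


# --- qc_lab_values ----------------------------------------------------------

def _long(values, var="x"):
    return pd.DataFrame({"variable": var, "value": values})


def test_qc_median_2sd_rule_oracle():
    """Direct oracle: median 3, sample SD of {1,2,3,4,100}, test each value."""
    values = [1.0, 2.0, 3.0, 4.0, 100.0]
    med = float(np.median(values))
    sd = float(np.std(values, ddof=1))
    expected = sorted(v for v in values if abs(v - med) <= 2 * sd)
    assert expected == [1.0, 2.0, 3.0, 4.0]  # frozen from the oracle
    out = dn.qc_lab_values(_long(values))
    assert sorted(out["value"]) == expected


def test_qc_identical_values_kept():
    out = dn.qc_lab_values(_long([7.0] * 6))
    assert len(out) == 6


def test_qc_range_bound_dropped_regardless():
    out = dn.qc_lab_values(_long([5.0, 6.0, 7.0, 0.5]), bounds={"x": (1.0, 100.0)})
    assert 0.5 not in set(out["value"])


def test_qc_never_drops_inliers():
    rng = np.random.default_rng(0)
    values = rng.normal(50, 5, 200)
    out = dn.qc_lab_values(_long(values), bounds={"x": (0, 100)})
    med, sd = np.median(values), np.std(values, ddof=1)
    inliers = [v for v in values if abs(v - med) <= 2 * sd and 0 <= v <= 100]
    assert set(np.round(out["value"], 9)) >= set(np.round(inliers, 9))


def test_qc_wide_table_matches_long():
    wide = pd.DataFrame({
        "STUDYID": [1, 2, 3, 4, 5], "AGE": [60] * 5,
        "DAYS_VIS_INDEX": [400] * 5, "INDEX_AGE": [58] * 5,
        "x": [1.0, 2.0, 3.0, 4.0, 100.0],
    })
    out = qc_clinical_table(wide)
    assert out["x"].dropna().tolist() == [1.0, 2.0, 3.0, 4.0]


# --- fit_quartiles / quartile_level ----------------------------------------

def test_quartiles_nearest_rank():
    assert dn.fit_quartiles(range(1, 9), "v").cuts == (2.0, 4.0, 6.0)
    assert dn.fit_quartiles(range(1, 101), "v").cuts == (25.0, 50.0, 75.0)


def test_quartiles_constant_values():
    b = dn.fit_quartiles([5.0] * 10, "v")
    assert b.cuts == (5.0, 5.0, 5.0)
    assert dn.quartile_level(5.0, b) == 0  # ties go down


def test_quartiles_insufficient_data():
    with pytest.raises(ValueError):
        dn.fit_quartiles([1.0, 2.0, 3.0], "v")


@given(st.floats(allow_nan=False, allow_infinity=False, width=32))
@settings(derandomize=True, max_examples=200)
def test_quartile_level_partitions(value):
    b = QuartileBoundaries("v", (10.0, 20.0, 30.0))
    level = dn.quartile_level(value, b)
    assert level in (0, 1, 2, 3)
    # ties-down rule: value equal to a cut maps to the bin below it
    if value <= 10.0:
        assert level == 0
    elif value <= 20.0:
        assert level == 1
    elif value <= 30.0:
        assert level == 2
    else:
        assert level == 3


# --- tokenize ---------------------------------------------------------------

@pytest.fixture
def boundaries():
    return {
        "age": QuartileBoundaries("age", (50.0, 60.0, 70.0)),
        "egfr": QuartileBoundaries("egfr", (25.0, 50.0, 75.0)),
    }


def test_repeat_subtype_codes_collapse_to_one_token(boundaries):
    tokens = dn.tokenize_patient(
        {"GENDER": "M", "RACE": "W", "INDEX_AGE": 55},
        events=[(400, "I50.22"), (500, "I50.9")],
        labs=[],
        boundaries=boundaries,
    )
    dx = [t for t in tokens if t.kind == "diagnosis"]
    assert dx == [FeatureToken("diagnosis", "I50", "present")]


def test_egfr_band_maps_to_quartile_one(boundaries):
    tokens = dn.tokenize_patient(
        {"GENDER": "F", "RACE": "W", "INDEX_AGE": 45},
        events=[], labs=[(400, "egfr", 30.0), (500, "egfr", 40.0)],
        boundaries=boundaries, status_rules={},
    )
    assert FeatureToken("clinical_quartile", "egfr", "1") in tokens
    assert FeatureToken("demographic", "age_quartile", "0") in tokens


def test_no_labs_gives_demographic_and_diagnosis_only(boundaries):
    tokens = dn.tokenize_patient(
        {"GENDER": "M", "RACE": "W", "INDEX_AGE": 65},
        events=[(400, "D01")], labs=[], boundaries=boundaries,
    )
    kinds = {t.kind for t in tokens}
    assert kinds == {"demographic", "diagnosis"}


def test_status_rule_tokens(boundaries):
    rules = {"creatinine": DEFAULT_STATUS_RULES["creatinine"]}
    tokens = dn.tokenize_patient(
        {"GENDER": "M", "RACE": "W", "INDEX_AGE": 65},
        events=[], labs=[(400, "creatinine", 2.0)],
        boundaries=boundaries, status_rules=rules,
    )
    assert FeatureToken("clinical_status", "creatinine", "abnormal") in tokens


def test_tokenize_order_invariance(boundaries):
    record = {"GENDER": "M", "RACE": "W", "INDEX_AGE": 55}
    events = [(400, "D01"), (500, "D02"), (450, "I50.9")]
    a = dn.tokenize_patient(record, events, [], boundaries)
    b = dn.tokenize_patient(record, list(reversed(events)), [], boundaries)
    assert a == b


def test_cohort_tokenizer_matches_per_patient(planted_cohort):
    """The vectorised cohort path produces exactly the per-patient sets."""
    patients, dx, clinical, _ = planted_cohort
    ev, labs = dn.window_features(dx, clinical, complication="kidney")
    boundaries = {
        "age": dn.fit_quartiles(patients["INDEX_AGE"], "age"),
        "egfr": dn.fit_quartiles(clinical["egfr"].dropna(), "egfr"),
    }
    sets = dn.tokenize_cohort(patients, ev, labs, boundaries, status_rules={})
    sample = patients.sample(25, random_state=1)
    for row in sample.itertuples():
        sid = row.STUDYID
        events = list(zip(ev.loc[ev["STUDYID"] == sid, "DX_INDEX"],
                          ev.loc[ev["STUDYID"] == sid, "DX_CODE"]))
        lab_rows = labs[labs["STUDYID"] == sid]
        lab_facts = [
            (r.DAYS_VIS_INDEX, "egfr", r.egfr)
            for r in lab_rows.itertuples() if np.isfinite(r.egfr)
        ]
        expected = dn.tokenize_patient(
            {"GENDER": row.GENDER, "RACE": row.RACE, "INDEX_AGE": row.INDEX_AGE},
            events, lab_facts, boundaries, status_rules={},
        )
        assert sets[sid] == expected


# --- filters ----------------------------------------------------------------

def test_prevalence_ceiling_rule():
    sets = {i: frozenset() for i in range(200)}
    rare = FeatureToken("diagnosis", "D01", "present")
    common = FeatureToken("diagnosis", "D02", "present")
    sets[0] = frozenset({rare, common})
    for i in range(1, 200):
        sets[i] = frozenset({common})
    kept = dn.prevalence_filter(sets, min_frac=0.01)  # needs ceil(2.0)=2 carriers
    assert rare not in kept and common in kept


def test_prevalence_min_frac_zero_keeps_all():
    t = FeatureToken("diagnosis", "D01", "present")
    sets = {1: frozenset({t}), 2: frozenset()}
    assert t in dn.prevalence_filter(sets, min_frac=0.0)


def test_prevalence_every_retained_token_reaches_floor(planted_cohort):
    patients, dx, clinical, _ = planted_cohort
    ev, labs = dn.window_features(dx, clinical, complication="kidney")
    sets = dn.tokenize_cohort(patients, ev, labs, {}, status_rules={})
    kept = dn.prevalence_filter(sets, 0.01)
    n = len(sets)
    for token in kept:
        assert sum(token in s for s in sets.values()) >= int(np.ceil(0.01 * n))


@pytest.mark.parametrize("counts,expected_kept", [
    ({"a": 4, "b": 5, "c": 6, "d": 7, "e": 8}, ["b", "c", "d", "e"]),
    ({"a": 5, "b": 5, "c": 5}, ["a", "b", "c"]),
    ({"a": 5, "b": 20}, ["a", "b"]),  # median 12.5 -> cap 25
])
def test_patient_filters(counts, expected_kept):
    kept, _ = dn.patient_filters(counts)
    assert kept == expected_kept


def test_patient_filters_cap_uses_pre_removal_median():
    counts = {"a": 5, "b": 6, "c": 7, "d": 50}
    kept, med = dn.patient_filters(counts)
    assert med == 6.5  # median over all four, before any removal
    assert "d" not in kept


def test_balance_downsamples_to_smaller_class():
    fast = [f"f{i}" for i in range(100)]
    slow = [f"s{i}" for i in range(80)]
    f, s = dn.balance_classes(fast, slow, seed=0)
    assert len(f) == len(s) == 80
    assert set(f) <= set(fast) and set(s) == set(slow)


def test_balance_equal_sizes_identity():
    f, s = dn.balance_classes(["a", "b"], ["c", "d"], seed=5)
    assert (f, s) == (["a", "b"], ["c", "d"])


def test_balance_seed_deterministic():
    fast = [f"f{i}" for i in range(50)]
    slow = [f"s{i}" for i in range(30)]
    assert dn.balance_classes(fast, slow, seed=3) == dn.balance_classes(fast, slow, seed=3)


def test_balance_empty_class_rejected():
    with pytest.raises(ValueError):
        dn.balance_classes([], ["a"], seed=0)
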