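"""Synthetic longitudinal EHR cohorts with planted fast/slow structure.

Real cohorts for this analysis live in private health-information exchanges,
so this module generates the three flat tables the pipeline consumes —
diagnosis events, patient demographics and clinical lab panels — together
with ground-truth progressor labels. Every patient receives a type-2-diabetes
index event at day 0, a complication event whose day is drawn from the
label's time-to-complication distribution, and a set of binary "planted"
features whose prevalence differs between fast and slow progressors by a
known amount. Because the generative model is fully specified, the exact
Bayes posterior (and hence an upper bound on achievable AUC) is computable,
giving every downstream stage a quantitative oracle.

The schemas mirror a de-identified EHR extract: all timestamps are integer
day offsets from the diabetes index date (day 0), diagnosis codes are ICD-9
or ICD-10 strings, and lab panels are sparse per-visit measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import COMPLICATION_CODES, complication_prefixes

__all__ = [
    "PlantedFeature",
    "LabSpec",
    "SyntheticCohortConfig",
    "default_planted",
    "generate_cohort",
    "expected_node_weight",
    "planted_bayes_auc",
    "write_cohort",
    "read_cohort",
]

# Column layouts of the three input tables plus the truth-label table.
DIAGNOSIS_COLUMNS = ("STUDYID", "DX_INDEX", "DX_CODE")
PATIENT_COLUMNS = ("STUDYID", "INDEX_YEAR", "INDEX_AGE", "GENDER", "RACE")
CLINICAL_BASE_COLUMNS = ("STUDYID", "AGE", "DAYS_VIS_INDEX", "INDEX_AGE")
TRUTH_COLUMNS = ("STUDYID", "COMPLICATION", "DAYS_TO_COMPLICATION", "LABEL")

# Letters usable for synthetic 3-character diagnosis codes. None of these can
# prefix-match the T2DM inclusion list or any complication list (which use
# only E/G/H/I/K/N and numeric prefixes). "F" is reserved for planted
# features, the rest for background noise.
_PLANTED_LETTER = "F"
_BACKGROUND_LETTERS = "DJLMPQRSTUWXYZ"


@dataclass(frozen=True)
class PlantedFeature:
    """A binary feature whose prevalence separates fast from slow progressors.

    ``p_fast`` / ``p_slow`` are the probabilities that a fast / slow
    progressor exhibits the feature inside the feature window. ``kind``
    controls how the feature is materialised:

    - ``diagnosis``: ``token_id`` is emitted as an ICD code at a random
      in-window day.
    - ``demographic``: ``token_id`` has the form ``"GENDER=M"`` or
      ``"RACE=<value>"``; the patient's demographic field is set to that
      value when the feature fires, to a default otherwise.
    - ``clinical``: ``token_id`` names a lab variable in the panel; when the
      feature fires the patient's values for that variable are drawn from a
      mean-shifted component, so the informative quartile arises from the
      measurements themselves rather than from a written token.
    """

    token_id: str
    p_fast: float
    p_slow: float
    kind: str = "diagnosis"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fast <= 1.0 or not 0.0 <= self.p_slow <= 1.0:
            raise ValueError(
                f"planted feature {self.token_id!r}: probabilities must lie "
                f"in [0, 1], got p_fast={self.p_fast}, p_slow={self.p_slow}"
            )
        if self.kind not in ("diagnosis", "demographic", "clinical"):
            raise ValueError(f"unknown planted-feature kind {self.kind!r}")


@dataclass(frozen=True)
class LabSpec:
    """Sampling distribution of one lab variable.

    Values are Gaussian with ``mean``/``sd``; a planted clinical feature
    named after this variable shifts the mean by ``shift`` when it fires.
    """

    name: str
    mean: float
    sd: float
    shift: float = 0.0


DEFAULT_LAB_PANEL: tuple[LabSpec, ...] = (
    LabSpec("egfr", mean=90.0, sd=20.0, shift=-40.0),
    LabSpec("hba1c", mean=7.5, sd=1.2, shift=2.0),
    LabSpec("glucose", mean=140.0, sd=40.0, shift=60.0),
)


@dataclass
class SyntheticCohortConfig:
    """Full description of a synthetic cohort.

    The same config plus seed always reproduces byte-identical tables.
    Day-offset defaults place fast progressors' complications inside the
    second year after the index date (days 366-730) and slow progressors'
    in years 4-5 (days 1096-1825), so the two groups are cleanly separated
    while all planted evidence lives inside the second-year feature window.
    """

    n_patients: int
    complication: str = "kidney"
    frac_fast: float = 0.5
    planted: Sequence[PlantedFeature] = ()
    n_background: int = 40
    background_prevalence: float = 0.15
    t_fast_range: tuple[int, int] = (366, 730)
    t_slow_range: tuple[int, int] = (1096, 1825)
    lab_panel: Sequence[LabSpec] = DEFAULT_LAB_PANEL
    min_diagnoses: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.complication not in COMPLICATION_CODES:
            raise ValueError(f"unknown complication {self.complication!r}")
        if not 0.0 < self.frac_fast < 1.0:
            raise ValueError("frac_fast must lie strictly inside (0, 1)")
        if not 0.0 <= self.background_prevalence <= 1.0:
            raise ValueError("background_prevalence must lie in [0, 1]")
        if len(self.planted) == 0 and self.n_background == 0:
            raise ValueError(
                "configuration has no features: provide at least one planted "
                "feature or a positive n_background"
            )
        lo_f, hi_f = self.t_fast_range
        lo_s, hi_s = self.t_slow_range
        if not (365 < lo_f <= hi_f):
            raise ValueError("fast time-to-complication support must lie in (365, t_max]")
        if (lo_s + hi_s) / 2 <= (lo_f + hi_f) / 2:
            raise ValueError("slow progressors must be later than fast in expectation")
        if self.n_background > len(_BACKGROUND_LETTERS) * 100:
            raise ValueError("n_background exceeds the synthetic code space")

    def background_codes(self) -> list[str]:
        """The 3-character synthetic codes used for background features."""
        pool = [f"{letter}{i:02d}" for letter in _BACKGROUND_LETTERS for i in range(100)]
        return pool[: self.n_background]


def default_planted(n: int, p_fast: float, p_slow: float) -> list[PlantedFeature]:
    """``n`` independent planted diagnosis features "F00", "F01", ..."""
    return [
        PlantedFeature(f"{_PLANTED_LETTER}{i:02d}", p_fast, p_slow, "diagnosis")
        for i in range(n)
    ]


def _empty_tables(config: SyntheticCohortConfig):
    lab_cols = [s.name for s in config.lab_panel]
    return (
        pd.DataFrame(columns=list(PATIENT_COLUMNS)),
        pd.DataFrame(columns=list(DIAGNOSIS_COLUMNS)),
        pd.DataFrame(columns=list(CLINICAL_BASE_COLUMNS) + lab_cols),
        pd.DataFrame(columns=list(TRUTH_COLUMNS)),
    )


def generate_cohort(config: SyntheticCohortConfig):
    """Generate one synthetic cohort.

    Returns ``(patients, diagnosis_events, lab_measurements, truth_labels)``
    as pandas DataFrames in the schemas of the de-identified extract. All
    randomness flows from ``config.seed`` through one generator, so identical
    configs reproduce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return _empty_tables(config)

    study_ids = np.arange(1_000_000, 1_000_000 + n)
    is_fast = rng.random(n) < config.frac_fast
    labels = np.where(is_fast, "fast", "slow")

    # --- demographics -----------------------------------------------------
    gender_feats = [f for f in config.planted if f.kind == "demographic"
                    and f.token_id.startswith("GENDER=")]
    race_feats = [f for f in config.planted if f.kind == "demographic"
                  and f.token_id.startswith("RACE=")]
    gender = np.where(rng.random(n) < 0.5, "M", "F")
    race = np.full(n, "UNKNOWN/NOT DOCUMENTED", dtype=object)
    for feat in gender_feats:
        value = feat.token_id.split("=", 1)[1]
        other = "F" if value == "M" else "M"
        p = np.where(is_fast, feat.p_fast, feat.p_slow)
        gender = np.where(rng.random(n) < p, value, other)
    for feat in race_feats:
        value = feat.token_id.split("=", 1)[1]
        p = np.where(is_fast, feat.p_fast, feat.p_slow)
        fires = rng.random(n) < p
        race = np.where(fires, value, race)

    index_age = np.clip(np.rint(rng.normal(60, 10, n)), 18, 95).astype(int)
    index_year = rng.integers(1995, 2016, n)
    patients = pd.DataFrame({
        "STUDYID": study_ids,
        "INDEX_YEAR": index_year,
        "INDEX_AGE": index_age,
        "GENDER": gender,
        "RACE": race,
    })

    # --- complication event & truth labels --------------------------------
    lo_f, hi_f = config.t_fast_range
    lo_s, hi_s = config.t_slow_range
    t_comp = np.where(
        is_fast,
        rng.integers(lo_f, hi_f + 1, n),
        rng.integers(lo_s, hi_s + 1, n),
    )
    truth = pd.DataFrame({
        "STUDYID": study_ids,
        "COMPLICATION": config.complication,
        "DAYS_TO_COMPLICATION": t_comp,
        "LABEL": labels,
    })

    # --- diagnosis events -------------------------------------------------
    sid_col: list[int] = []
    day_col: list[int] = []
    code_col: list[str] = []

    def emit(sid: int, day: int, code: str) -> None:
        sid_col.append(sid)
        day_col.append(day)
        code_col.append(code)

    comp_prefixes = complication_prefixes(config.complication)
    bg_codes = config.background_codes()
    n_bg = len(bg_codes)

    dx_feats = [f for f in config.planted if f.kind == "diagnosis"]
    p_dx = np.array([[f.p_fast, f.p_slow] for f in dx_feats], dtype=float)
    # presence[i, j]: patient i exhibits planted diagnosis feature j
    if dx_feats:
        group = (~is_fast).astype(int)  # 0 = fast, 1 = slow
        presence = rng.random((n, len(dx_feats))) < p_dx[:, group].T
    else:
        presence = np.zeros((n, 0), dtype=bool)
    bg_presence = (
        rng.random((n, n_bg)) < config.background_prevalence
        if n_bg else np.zeros((n, 0), dtype=bool)
    )

    for i in range(n):
        sid = int(study_ids[i])
        emit(sid, 0, "250.01")  # index T2DM diagnosis defines day 0
        comp_code = str(rng.choice(comp_prefixes)) + ".9"
        emit(sid, int(t_comp[i]), comp_code)

        in_window = 0
        for j, feat in enumerate(dx_feats):
            if presence[i, j]:
                emit(sid, int(rng.integers(366, 731)), feat.token_id)
                in_window += 1
        present_bg = set()
        for j in range(n_bg):
            if bg_presence[i, j]:
                emit(sid, int(rng.integers(366, 731)), bg_codes[j])
                present_bg.add(j)
                in_window += 1
        # top up sparse histories so nobody falls below the downstream
        # minimum-diagnoses filter for lack of any events at all
        if in_window < config.min_diagnoses and n_bg:
            available = [j for j in range(n_bg) if j not in present_bg]
            need = min(config.min_diagnoses - in_window, len(available))
            for j in rng.choice(len(available), size=need, replace=False):
                emit(sid, int(rng.integers(366, 731)), bg_codes[available[int(j)]])
                in_window += 1
        # label-independent noise outside the feature window, exercising the
        # second-year restriction downstream
        if rng.random() < 0.3 and n_bg:
            emit(sid, -int(rng.integers(1, 400)),
                 bg_codes[int(rng.integers(0, n_bg))])
        if rng.random() < 0.3 and n_bg:
            emit(sid, int(rng.integers(1, 366)),
                 bg_codes[int(rng.integers(0, n_bg))])

    diagnosis = pd.DataFrame({
        "STUDYID": np.asarray(sid_col, dtype=np.int64),
        "DX_INDEX": np.asarray(day_col, dtype=np.int64),
        "DX_CODE": code_col,
    }).sort_values(["STUDYID", "DX_INDEX", "DX_CODE"], kind="mergesort",
                   ignore_index=True)

    # --- lab measurements -------------------------------------------------
    clin_feats = {f.token_id: f for f in config.planted if f.kind == "clinical"}
    panel = list(config.lab_panel)
    shifted = {}
    for spec in panel:
        feat = clin_feats.get(spec.name)
        if feat is not None:
            group = (~is_fast).astype(int)
            p = np.array([feat.p_fast, feat.p_slow])[group]
            shifted[spec.name] = rng.random(n) < p
        else:
            shifted[spec.name] = np.zeros(n, dtype=bool)

    rows = []
    for i in range(n):
        sid = int(study_ids[i])
        n_visits = int(rng.integers(1, 4))
        days = rng.integers(366, 731, n_visits)
        for day in days:
            row = {
                "STUDYID": sid,
                "AGE": int(index_age[i] + day // 365),
                "DAYS_VIS_INDEX": int(day),
                "INDEX_AGE": int(index_age[i]),
            }
            for spec in panel:
                if rng.random() < 0.7:  # sparse panels: not every test each visit
                    mu = spec.mean + (spec.shift if shifted[spec.name][i] else 0.0)
                    row[spec.name] = round(float(rng.normal(mu, spec.sd)), 2)
            rows.append(row)
    clinical = pd.DataFrame(
        rows, columns=list(CLINICAL_BASE_COLUMNS) + [s.name for s in panel]
    ).sort_values(["STUDYID", "DAYS_VIS_INDEX"], kind="mergesort",
                  ignore_index=True)

    return patients, diagnosis, clinical, truth


def expected_node_weight(p_fast: float, p_slow: float, frac_fast: float = 0.5) -> float:
    """Expected network weight of a planted feature's node.

    Among patients carrying the feature, the expected fraction that are fast
    progressors is ``frac_fast*p_fast / (frac_fast*p_fast + (1-frac_fast)*p_slow)``
    — the population analogue of the node weight the network module estimates.
    """
    for name, p in (("p_fast", p_fast), ("p_slow", p_slow), ("frac_fast", frac_fast)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    num = frac_fast * p_fast
    den = num + (1.0 - frac_fast) * p_slow
    if den == 0.0:
        raise ValueError("node weight undefined: feature never occurs in either group")
    return num / den


def planted_bayes_auc(
    config: SyntheticCohortConfig,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo AUC of the exact posterior P(fast | planted features).

    Under the generative model the planted features are conditionally
    independent Bernoullis given the label, so the posterior log-odds is the
    sum of per-feature log-likelihood ratios. The AUC of that posterior
    upper-bounds (in expectation) what any classifier reading only the
    planted features can achieve, which makes this the end-to-end oracle for
    pipeline evaluation.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if not config.planted:
        return 0.5
    rng = np.random.default_rng(config.seed if seed is None else seed)
    eps = 1e-12
    pf = np.clip(np.array([f.p_fast for f in config.planted]), eps, 1 - eps)
    ps = np.clip(np.array([f.p_slow for f in config.planted]), eps, 1 - eps)
    llr_present = np.log(pf) - np.log(ps)
    llr_absent = np.log1p(-pf) - np.log1p(-ps)

    is_fast = rng.random(n_mc) < config.frac_fast
    p = np.where(is_fast[:, None], pf[None, :], ps[None, :])
    x = rng.random((n_mc, len(pf))) < p
    scores = x @ llr_present + (~x) @ llr_absent
    # rank-based AUC with half credit for ties (local import avoids a cycle)
    from .evaluation import auc

    return auc(scores, is_fast)


def write_cohort(tables, outdir: str | Path) -> dict[str, Path]:
    """Write the four cohort tables as headered CSV files.

    Returns a mapping of table name to path. Missing lab panels are written
    as empty cells.
    """
    patients, diagnosis, clinical, truth = tables
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": outdir / "patients.csv",
        "diagnosis": outdir / "diagnosis.csv",
        "clinical": outdir / "clinical.csv",
        "truth": outdir / "truth.csv",
    }
    patients.to_csv(paths["patients"], index=False)
    diagnosis.to_csv(paths["diagnosis"], index=False)
    clinical.to_csv(paths["clinical"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths


def read_cohort(indir: str | Path):
    """Read tables written by :func:`write_cohort`."""
    indir = Path(indir)
    patients = pd.read_csv(indir / "patients.csv")
    diagnosis = pd.read_csv(indir / "diagnosis.csv", dtype={"DX_CODE": str})
    clinical = pd.read_csv(indir / "clinical.csv")
    truth_path = indir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return patients, diagnosis, clinical, truth
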