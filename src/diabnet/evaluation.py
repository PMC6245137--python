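"""Evaluation protocol: repeated stratified holdout, AUC/sensitivity/
specificity, the element-budget sweep, and between-complication correlation.

Each repeat draws a fresh stratified 80/20 split of the labeled, balanced
cohort, fits the entire pipeline (lab QC, quartile boundaries, patient
filters, prevalence filter, network construction and pruning) on the
training split only, scores the held-out patients, and records rank-based
AUC plus sensitivity/specificity at a configurable threshold. Metrics are
aggregated as mean and SD over repeats, per complication and per element
budget ``n``.

Training/test isolation is strict by construction: fitting reads only rows
belonging to training patients, so no test record can influence quartile
boundaries, filters or network counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import WINDOW, detect_complication_days, label_progressors, window_features
from .features import (
    DEFAULT_STATUS_RULES,
    QuartileBoundaries,
    StatusRule,
    balance_classes,
    fit_quartiles,
    patient_filters,
    prevalence_filter,
    qc_clinical_table,
    tokenize_cohort,
)
from .network import HeteroNetwork, build_network, prune, z_critical
from .scoring import DEFAULT_N_GRID, match_elements, score_patient, sweep_n

__all__ = [
    "PipelineConfig",
    "PipelineModel",
    "ExperimentResult",
    "split_patients",
    "auc",
    "sens_spec",
    "roc_points",
    "fit_pipeline",
    "score_cohort",
    "run_experiment",
    "progressor_correlation",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable stage parameters, defaulting to the study protocol."""

    window: tuple[int, int] = WINDOW
    q_fast: float = 0.25
    q_slow: float = 0.75
    min_frac: float = 0.01          # node prevalence filter
    min_diagnoses: int = 5
    cap_multiplier: float = 2.0     # x median diagnosis-count cap
    count_distinct: bool = False    # count events (False) or distinct codes
    alpha: float = 0.05             # two-sided significance for pruning
    n_max: int = 12                 # element budget in scoring
    remove_lowest: bool = True
    threshold: float = 0.5          # classification threshold for sens/spec
    test_frac: float = 0.2
    repeats: int = 5
    lab_summary: str = "mean"
    lab_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fast_day_cap: int | None = None


@dataclass
class PipelineModel:
    """Everything fitted on a training split, sufficient to score anyone."""

    complication: str
    config: PipelineConfig
    boundaries: dict[str, QuartileBoundaries]
    status_rules: Mapping[str, StatusRule]
    universe: set
    network: HeteroNetwork       # pruned
    full_network: HeteroNetwork  # before pruning (diagnostics)
    z_crit: float
    eps: float
    train_ids: list              # balanced training patients actually used
    median_diagnoses: float


@dataclass
class ExperimentResult:
    complication: str
    per_split: pd.DataFrame   # columns: complication, n_max, split, auc, sensitivity, specificity
    summary: pd.DataFrame     # mean/SD over splits per n_max
    seeds: list[int]


def split_patients(
    labels: Mapping,
    test_frac: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list, list]:
    """Seed-deterministic (stratified) train/test split of labeled patients.

    Returns disjoint, exhaustive, sorted id lists. With stratification each
    class contributes its own ``test_frac`` share, so class balance in the
    test set tracks the training set to within one patient per class.
    """
    by_class: dict[str, list] = {}
    for sid, lab in labels.items():
        by_class.setdefault(lab, []).append(sid)
    if stratify and any(len(v) < 2 for v in by_class.values()):
        raise ValueError("split_patients: need >= 2 patients per class")
    if not by_class:
        raise ValueError("split_patients: no patients")
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    groups = by_class.values() if stratify else [sum(by_class.values(), [])]
    for ids in groups:
        ids = sorted(ids, key=str)
        perm = rng.permutation(len(ids))
        n_test = max(1, int(round(test_frac * len(ids))))
        test.extend(ids[i] for i in perm[:n_test])
        train.extend(ids[i] for i in perm[n_test:])
    return sorted(train, key=str), sorted(test, key=str)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(
        [lab == "fast" if isinstance(lab, str) else bool(lab) for lab in labels]
    )
    if y.all() or (~y).all():
        raise ValueError("metric undefined: both classes must be present")
    return y


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties.

    Equals P(score_fast > score_slow) + 0.5 P(tie) over all fast/slow pairs.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sens_spec(scores, labels, threshold: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity with fast = positive, score >= t = fast."""
    y = _as_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    return tp / (tp + fn), tn / (tn + fp)


def roc_points(scores, labels) -> pd.DataFrame:
    """Full ROC curve (FPR, TPR, threshold) so any operating point is visible."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    rows = []
    n1, n0 = int(y.sum()), int((~y).sum())
    for t in thresholds:
        pred = s >= t
        rows.append({
            "THRESHOLD": t,
            "TPR": float((pred & y).sum() / n1),
            "FPR": float((pred & ~y).sum() / n0),
        })
    return pd.DataFrame(rows)


def _windowed_diagnosis_counts(events_w: pd.DataFrame, ids, distinct: bool) -> dict:
    sub = events_w[events_w["STUDYID"].isin(set(ids))]
    if distinct:
        counts = sub.groupby("STUDYID")["DX_CODE"].nunique()
    else:
        counts = sub.groupby("STUDYID")["DX_CODE"].size()
    out = {sid: 0 for sid in ids}
    out.update(counts.to_dict())
    return out


def fit_pipeline(
    patients: pd.DataFrame,
    diagnosis: pd.DataFrame,
    clinical: pd.DataFrame | None,
    labels: Mapping,
    train_ids: Sequence,
    complication: str,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    status_rules: Mapping[str, StatusRule] | None = None,
) -> PipelineModel:
    """Fit the full feature/network pipeline on the training patients only.

    Order of operations: restrict every table to ``train_ids``; window events
    and labs (stripping the outcome complication's codes); apply the
    minimum/2x-median diagnosis-count filter (median from this training
    split); balance fast vs slow by downsampling; QC lab values; fit age and
    lab quartile boundaries; tokenize; drop tokens below the prevalence
    floor; build and prune the network.
    """
    status_rules = DEFAULT_STATUS_RULES if status_rules is None else status_rules
    train_ids = [sid for sid in train_ids if labels.get(sid) in ("fast", "slow")]
    if not train_ids:
        raise ValueError("fit_pipeline: no labeled training patients")
    idset = set(train_ids)

    pats = patients[patients["STUDYID"].isin(idset)]
    ev = diagnosis[diagnosis["STUDYID"].isin(idset)]
    cl = clinical[clinical["STUDYID"].isin(idset)] if clinical is not None else None
    ev_w, cl_w = window_features(ev, cl, complication=complication, window=config.window)

    counts = _windowed_diagnosis_counts(ev_w, train_ids, config.count_distinct)
    kept, med = patient_filters(counts, config.min_diagnoses, config.cap_multiplier)
    if not kept:
        raise ValueError("fit_pipeline: patient filters removed every training patient")

    fast = [sid for sid in kept if labels[sid] == "fast"]
    slow = [sid for sid in kept if labels[sid] == "slow"]
    if not fast or not slow:
        raise ValueError("fit_pipeline: one class empty after patient filters")
    fast, slow = balance_classes(fast, slow, seed=seed)
    used = set(fast) | set(slow)

    pats = pats[pats["STUDYID"].isin(used)]
    ev_w = ev_w[ev_w["STUDYID"].isin(used)]
    if cl_w is not None:
        cl_w = qc_clinical_table(cl_w[cl_w["STUDYID"].isin(used)], config.lab_bounds)

    boundaries: dict[str, QuartileBoundaries] = {}
    ages = pats["INDEX_AGE"].dropna().astype(float)
    if len(ages) >= 4:
        boundaries["age"] = fit_quartiles(ages, "age")
    if cl_w is not None and len(cl_w):
        base = {"STUDYID", "AGE", "DAYS_VIS_INDEX", "INDEX_AGE"}
        for var in [c for c in cl_w.columns if c not in base]:
            if var in status_rules:
                continue  # dichotomised, not quartiled
            summaries = cl_w[["STUDYID", var]].dropna().groupby("STUDYID")[var].mean()
            if len(summaries) >= 4:
                boundaries[var] = fit_quartiles(summaries.to_numpy(), var)

    token_sets = tokenize_cohort(pats, ev_w, cl_w, boundaries, status_rules,
                                 config.lab_summary)
    universe = prevalence_filter(token_sets, config.min_frac)
    token_sets = {sid: frozenset(t for t in s if t in universe)
                  for sid, s in token_sets.items()}

    net = build_network(token_sets, labels)
    pruned = prune(net, config.alpha)
    eps = 1.0 / (net.n_fast + net.n_slow + 2)
    return PipelineModel(
        complication=complication,
        config=config,
        boundaries=boundaries,
        status_rules=status_rules,
        universe=universe,
        network=pruned,
        full_network=net,
        z_crit=z_critical(config.alpha),
        eps=eps,
        train_ids=sorted(used, key=str),
        median_diagnoses=med,
    )


def score_cohort(
    model: PipelineModel,
    patients: pd.DataFrame,
    diagnosis: pd.DataFrame,
    clinical: pd.DataFrame | None,
    ids: Sequence,
    n_values: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Score patients against a fitted model.

    Returns a long DataFrame (STUDYID, COMPLICATION, N_MAX, PROBABILITY,
    N_USED, REMOVED_ELEMENT) with one row per patient per element budget;
    ``n_values=None`` scores only at the model's configured ``n_max``.
    """
    cfg = model.config
    if n_values is None:
        n_values = (cfg.n_max,)
    idset = set(ids)
    pats = patients[patients["STUDYID"].isin(idset)]
    ev = diagnosis[diagnosis["STUDYID"].isin(idset)]
    cl = clinical[clinical["STUDYID"].isin(idset)] if clinical is not None else None
    ev_w, cl_w = window_features(ev, cl, complication=model.complication,
                                 window=cfg.window)
    if cl_w is not None:
        cl_w = qc_clinical_table(cl_w, cfg.lab_bounds)
    token_sets = tokenize_cohort(pats, ev_w, cl_w, model.boundaries,
                                 model.status_rules, cfg.lab_summary)
    rows = []
    for sid in sorted(idset & set(token_sets), key=str):
        tokens = {t for t in token_sets[sid] if t in model.universe}
        candidates = match_elements(model.network, tokens, model.z_crit)
        scores = sweep_n(candidates, n_values, cfg.remove_lowest, model.eps, sid)
        for n, rs in scores.items():
            rows.append({
                "STUDYID": sid,
                "COMPLICATION": model.complication,
                "N_MAX": n,
                "PROBABILITY": rs.probability,
                "N_USED": rs.n_used,
                "REMOVED_ELEMENT": (
                    str(rs.removed_element.element) if rs.removed_element else ""
                ),
            })
    return pd.DataFrame(rows)


def run_experiment(
    patients: pd.DataFrame,
    diagnosis: pd.DataFrame,
    clinical: pd.DataFrame | None,
    complication: str,
    config: PipelineConfig = PipelineConfig(),
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    seed: int = 0,
) -> ExperimentResult:
    """Label, then repeat: split, fit on train, score test, measure.

    Labels come from the first complication-matching diagnosis of each
    patient (quartile-based fast/slow assignment); each repeat uses a fresh
    stratified split and an independently seeded class-balancing draw. The
    summary reports mean and population SD over repeats per element budget.
    """
    comp_days = detect_complication_days(diagnosis, complication)
    labels_df = label_progressors(
        comp_days, complication, config.q_fast, config.q_slow,
        min_days=config.window[0], fast_day_cap=config.fast_day_cap,
    )
    labels = {
        row.STUDYID: row.LABEL
        for row in labels_df.itertuples()
        if row.LABEL in ("fast", "slow")
    }
    if not labels:
        raise ValueError(f"run_experiment[{complication}]: no labeled patients")

    seeds = [int(s % (2**31)) for s in
             np.random.SeedSequence(seed).generate_state(2 * config.repeats)]
    rows = []
    for r in range(config.repeats):
        split_seed, balance_seed = seeds[2 * r], seeds[2 * r + 1]
        train_ids, test_ids = split_patients(labels, config.test_frac, split_seed)
        try:
            model = fit_pipeline(patients, diagnosis, clinical, labels, train_ids,
                                 complication, config, seed=balance_seed)
        except ValueError as exc:
            raise ValueError(f"fit stage failed on split {r}: {exc}") from exc
        scored = score_cohort(model, patients, diagnosis, clinical, test_ids,
                              n_values=n_grid)
        for n in n_grid:
            sub = scored[scored["N_MAX"] == int(n)]
            y = [labels[sid] for sid in sub["STUDYID"]]
            a = auc(sub["PROBABILITY"], y)
            sens, spec = sens_spec(sub["PROBABILITY"], y, config.threshold)
            rows.append({
                "complication": complication, "n_max": int(n), "split": r,
                "auc": a, "sensitivity": sens, "specificity": spec,
            })
    per_split = pd.DataFrame(rows)
    g = per_split.groupby("n_max")
    summary = pd.DataFrame({"n_max": sorted(set(int(n) for n in n_grid))})
    for metric in ("auc", "sensitivity", "specificity"):
        summary[f"{metric}_mean"] = g[metric].mean().reindex(summary["n_max"]).to_numpy()
        # population SD so a single repeat reports 0 spread, not NaN
        summary[f"{metric}_sd"] = (
            g[metric].agg(lambda v: float(np.std(v))).reindex(summary["n_max"]).to_numpy()
        )
    return ExperimentResult(complication, per_split, summary, seeds)


def progressor_correlation(labels_by_complication: Mapping) -> pd.DataFrame:
    """Pearson (phi) correlation of fast-progressor status between complications.

    For each pair, the correlation is computed over patients labeled fast or
    slow for both complications; empty or constant overlaps yield NaN. The
    matrix is symmetric by construction; the diagonal is left out (NaN).
    """
    comps = sorted(labels_by_complication)
    mat = pd.DataFrame(np.nan, index=comps, columns=comps, dtype=float)
    binary = {
        c: {sid: 1.0 if lab == "fast" else 0.0
            for sid, lab in labels_by_complication[c].items()
            if lab in ("fast", "slow")}
        for c in comps
    }
    for i, a in enumerate(comps):
        for b in comps[i + 1:]:
            shared = sorted(set(binary[a]) & set(binary[b]), key=str)
            if len(shared) < 2:
                continue
            x = np.array([binary[a][s] for s in shared])
            y = np.array([binary[b][s] for s in shared])
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat
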