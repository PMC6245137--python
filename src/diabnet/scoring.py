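"""Risk scoring: probability a patient is a fast progressor.

A test patient's history is matched against the pruned training network:
every significant node whose token the patient carries, and every
significant edge with both endpoints present, becomes a candidate element.
The ``n`` most significant candidates (by |z|, ``n <= 12`` by default) are
selected; the single lowest-weight element among them is then dropped —
empirically this boosts the signal of the fast-progression elements. With
surviving weights w_i the score is the naive-Bayes-style posterior

    p_t = prod(w_i),  p_f = prod(1 - w_i),  P(fast) = p_t / (p_t + p_f),

treating elements as equally likely and statistically independent. Patients
matching no significant element receive the uninformative 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FeatureToken
from .network import ElementStats, HeteroNetwork, element_key

__all__ = ["RiskScore", "match_elements", "score_patient", "sweep_n"]

DEFAULT_N_GRID: tuple[int, ...] = (7, 10, 12, 15, 17, 20)


@dataclass(frozen=True)
class RiskScore:
    """Outcome of scoring one patient."""

    probability: float
    used_elements: tuple[ElementStats, ...]
    n_used: int
    removed_element: ElementStats | None
    study_id: object = None


def match_elements(
    network: HeteroNetwork,
    token_set: Iterable[FeatureToken],
    z_crit: float = 1.959964,
) -> list[ElementStats]:
    """Candidate elements of a (pruned) network present in a patient history.

    Nodes match when the patient carries the token; edges when both endpoint
    tokens are present. The matched sub-network may be disconnected.
    """
    present = set(token_set)
    out: list[ElementStats] = []
    for token in network.node_counts:
        if token in present:
            out.append(network.stats(token, z_crit))
    for a, b in network.edge_counts:
        if a in present and b in present:
            out.append(network.stats((a, b), z_crit))
    out.sort(key=lambda s: element_key(s.element))
    return out


def _selection_order(s: ElementStats) -> tuple:
    # most significant first; ties: higher weight, then lexicographic identity
    return (-abs(s.z), -s.weight, element_key(s.element))


def score_patient(
    candidates: Sequence[ElementStats],
    n_max: int | None = 12,
    remove_lowest: bool = True,
    eps: float = 1e-9,
    study_id: object = None,
) -> RiskScore:
    """Score one patient from their matched candidate elements.

    ``n_max=None`` means unbounded selection. The removal of the
    lowest-weight selected element only happens when at least two elements
    were selected (otherwise nothing would remain). Weights are clamped to
    ``[eps, 1-eps]`` before the product so that degenerate 0/1 weights cannot
    produce 0/0.
    """
    if n_max is not None and n_max < 1:
        raise ValueError("n_max must be >= 1 (or None for unbounded)")
    ordered = sorted(candidates, key=_selection_order)
    selected = ordered if n_max is None else ordered[:n_max]
    if not selected:
        return RiskScore(0.5, (), 0, None, study_id)

    removed: ElementStats | None = None
    if remove_lowest and len(selected) >= 2:
        min_w = min(s.weight for s in selected)
        for i, s in enumerate(selected):  # first minimal in selection order
            if s.weight == min_w:
                removed = s
                selected = selected[:i] + selected[i + 1:]
                break

    w = np.clip(np.array([s.weight for s in selected], dtype=float), eps, 1.0 - eps)
    p_t = float(np.prod(w))
    p_f = float(np.prod(1.0 - w))
    probability = p_t / (p_t + p_f)
    return RiskScore(probability, tuple(selected), len(selected), removed, study_id)


def sweep_n(
    candidates: Sequence[ElementStats],
    n_values: Sequence[int] = DEFAULT_N_GRID,
    remove_lowest: bool = True,
    eps: float = 1e-9,
    study_id: object = None,
) -> dict[int, RiskScore]:
    """Score the same candidate list at each element budget in ``n_values``."""
    if not n_values:
        raise ValueError("sweep_n: n_values must be nonempty")
    return {
        int(n): score_patient(candidates, n_max=int(n), remove_lowest=remove_lowest,
                              eps=eps, study_id=study_id)
        for n in n_values
    }
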