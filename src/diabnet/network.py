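"""The heterogeneous comorbidity network and its significance pruning.

Training patients are split into fast and slow progressors. Every patient
contributes their token set as a clique: each token is a node and every
unordered pair of distinct tokens is an edge, counted once per patient (set
semantics — multiplicity within a history does not matter because weights
are defined over patients). Each element (node or edge) then carries

- ``k_fast`` / ``k_slow``: how many fast / slow patients contain it,
- ``weight = k_fast / (k_fast + k_slow)``: the fraction of its carriers that
  are fast progressors — the per-element probability used in risk scoring,
- ``z``: the pooled two-proportion Z statistic comparing the element's
  prevalence between the fast and slow groups.

Pruning removes every element whose |z| falls below the two-sided critical
value (95% confidence by default); only the surviving, significant elements
participate in scoring. No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .features import FeatureToken

__all__ = [
    "ElementStats",
    "HeteroNetwork",
    "two_proportion_z",
    "build_network",
    "prune",
    "top_conditions",
    "write_network",
    "to_graphml",
]

Element = FeatureToken | tuple[FeatureToken, FeatureToken]


def element_key(element: Element) -> tuple:
    """Deterministic total order over nodes and edges (nodes sort first)."""
    if isinstance(element, FeatureToken):
        return (0, (element.kind, element.name, element.level))
    a, b = element
    return (1, (a.kind, a.name, a.level), (b.kind, b.name, b.level))


@dataclass(frozen=True)
class ElementStats:
    """Counts, weight and Z statistic of one network element."""

    element: Element
    k_fast: int
    k_slow: int
    weight: float
    z: float
    significant: bool


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled two-proportion Z statistic for k1/n1 versus k2/n2.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled proportion
    p = (k1+k2)/(n1+n2). Degenerate pools (p equal to 0 or 1, where both
    sample proportions necessarily coincide) return 0.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("two_proportion_z: group sizes must be >= 1")
    if not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("two_proportion_z: counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled == 0.0 or pooled == 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (k1 / n1 - k2 / n2) / se


def _z_vec(k1: np.ndarray, n1: int, k2: np.ndarray, n2: int) -> np.ndarray:
    pooled = (k1 + k2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        z = (k1 / n1 - k2 / n2) / se
    return np.where((pooled == 0.0) | (pooled == 1.0), 0.0, z)


@dataclass
class HeteroNetwork:
    """Node and edge counters split by fast/slow label."""

    n_fast: int
    n_slow: int
    node_counts: dict = field(default_factory=dict)  # token -> (k_fast, k_slow)
    edge_counts: dict = field(default_factory=dict)  # (tok_a, tok_b) -> (k_fast, k_slow)

    def elements(self) -> list[Element]:
        nodes = sorted(self.node_counts, key=element_key)
        edges = sorted(self.edge_counts, key=element_key)
        return nodes + edges  # type: ignore[return-value]

    def counts(self, element: Element) -> tuple[int, int]:
        if isinstance(element, FeatureToken):
            return self.node_counts[element]
        return self.edge_counts[element]

    def stats(self, element: Element, z_crit: float = 1.959964) -> ElementStats:
        k_fast, k_slow = self.counts(element)
        total = k_fast + k_slow
        if total == 0:
            raise ValueError(f"element {element} has zero carriers; weight undefined")
        weight = k_fast / total
        # a one-class cohort supports counting but carries no contrast
        z = (0.0 if self.n_fast == 0 or self.n_slow == 0
             else two_proportion_z(k_fast, self.n_fast, k_slow, self.n_slow))
        return ElementStats(element, k_fast, k_slow, weight, z, abs(z) >= z_crit)

    def all_stats(self, z_crit: float = 1.959964) -> list[ElementStats]:
        return [self.stats(e, z_crit) for e in self.elements()]


def build_network(token_sets: Mapping, labels: Mapping) -> HeteroNetwork:
    """Build the network from per-patient token sets and fast/slow labels.

    Each patient increments their label's counter on every token in their set
    and on every unordered pair of distinct tokens (the per-patient clique).
    Implemented as a boolean patient x token incidence matrix per class, with
    edge counts from its Gram matrix.
    """
    if not token_sets:
        raise ValueError("build_network: empty cohort")
    ids = sorted(token_sets, key=str)
    for sid in ids:
        if labels.get(sid) not in ("fast", "slow"):
            raise ValueError(f"patient {sid!r} lacks a fast/slow label")

    universe = sorted({t for s in token_sets.values() for t in s})
    index = {t: i for i, t in enumerate(universe)}
    n_tok = len(universe)

    mats = {}
    sizes = {}
    for lab in ("fast", "slow"):
        members = [sid for sid in ids if labels[sid] == lab]
        sizes[lab] = len(members)
        a = np.zeros((len(members), n_tok), dtype=np.int32)
        for r, sid in enumerate(members):
            for t in token_sets[sid]:
                a[r, index[t]] = 1
        mats[lab] = a

    node_k = {lab: mats[lab].sum(axis=0) for lab in ("fast", "slow")}
    gram = {lab: mats[lab].T @ mats[lab] for lab in ("fast", "slow")}

    node_counts = {
        universe[i]: (int(node_k["fast"][i]), int(node_k["slow"][i]))
        for i in range(n_tok)
        if node_k["fast"][i] + node_k["slow"][i] > 0
    }
    edge_counts = {}
    iu, ju = np.triu_indices(n_tok, k=1)
    kf = gram["fast"][iu, ju]
    ks = gram["slow"][iu, ju]
    nz = (kf + ks) > 0
    for i, j, a, b in zip(iu[nz], ju[nz], kf[nz], ks[nz]):
        edge_counts[(universe[int(i)], universe[int(j)])] = (int(a), int(b))

    return HeteroNetwork(sizes["fast"], sizes["slow"], node_counts, edge_counts)


def z_critical(alpha: float) -> float:
    """Two-sided critical value; alpha=0.05 -> 1.959964."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return float(norm.ppf(1.0 - alpha / 2.0))


def prune(network: HeteroNetwork, alpha: float = 0.05) -> HeteroNetwork:
    """Keep only elements whose |z| reaches the two-sided critical value.

    Applied to nodes and edges alike. ``alpha=1.0`` keeps everything.
    """
    crit = z_critical(alpha)
    nf, ns = network.n_fast, network.n_slow

    def survives(counts: dict) -> dict:
        if not counts:
            return {}
        items = list(counts.items())
        kf = np.array([v[0] for _, v in items], dtype=float)
        ks = np.array([v[1] for _, v in items], dtype=float)
        z = _z_vec(kf, nf, ks, ns)
        return {e: v for (e, v), zi in zip(items, z) if abs(zi) >= crit}

    return HeteroNetwork(nf, ns, survives(network.node_counts),
                         survives(network.edge_counts))


def top_conditions(network: HeteroNetwork, m: int, z_crit: float = 1.959964):
    """Top-``m`` nodes ranked by weight and, separately, by Z score.

    Mirrors the study's summary tables of the conditions most associated with
    fast progression. Ties break lexicographically on token identity. Returns
    ``(by_weight, by_z)`` lists of :class:`ElementStats`.
    """
    if m <= 0:
        return [], []
    stats = [network.stats(t, z_crit) for t in sorted(network.node_counts, key=element_key)]
    by_weight = sorted(stats, key=lambda s: (-s.weight, element_key(s.element)))[:m]
    by_z = sorted(stats, key=lambda s: (-s.z, element_key(s.element)))[:m]
    return by_weight, by_z


def _node_row(token: FeatureToken, counts, nf, ns):
    kf, ks = counts
    z = two_proportion_z(kf, nf, ks, ns)
    return {
        "KIND": token.kind, "NAME": token.name, "LEVEL": token.level,
        "K_FAST": kf, "K_SLOW": ks,
        "WEIGHT": kf / (kf + ks), "Z": z,
    }


def write_network(network: HeteroNetwork, outdir: str | Path) -> dict[str, Path]:
    """Serialize nodes.csv / edges.csv; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nf, ns = network.n_fast, network.n_slow
    nodes = pd.DataFrame(
        [_node_row(t, c, nf, ns)
         for t, c in sorted(network.node_counts.items(), key=lambda kv: element_key(kv[0]))]
    )
    edge_rows = []
    for (a, b), (kf, ks) in sorted(network.edge_counts.items(),
                                   key=lambda kv: element_key(kv[0])):
        edge_rows.append({
            "KIND_A": a.kind, "NAME_A": a.name, "LEVEL_A": a.level,
            "KIND_B": b.kind, "NAME_B": b.name, "LEVEL_B": b.level,
            "K_FAST": kf, "K_SLOW": ks,
            "WEIGHT": kf / (kf + ks),
            "Z": two_proportion_z(kf, nf, ks, ns),
        })
    edges = pd.DataFrame(edge_rows)
    paths = {"nodes": outdir / "nodes.csv", "edges": outdir / "edges.csv"}
    nodes.to_csv(paths["nodes"], index=False)
    edges.to_csv(paths["edges"], index=False)
    return paths


def to_graphml(network: HeteroNetwork, path: str | Path) -> None:
    """Export the network for visualisation (networkx GraphML)."""
    import networkx as nx

    g = nx.Graph(n_fast=network.n_fast, n_slow=network.n_slow)
    nf, ns = network.n_fast, network.n_slow
    for token, (kf, ks) in network.node_counts.items():
        g.add_node(str(token), kind=token.kind, name=token.name, level=token.level,
                   k_fast=kf, k_slow=ks, weight=kf / (kf + ks),
                   z=two_proportion_z(kf, nf, ks, ns))
    for (a, b), (kf, ks) in network.edge_counts.items():
        g.add_edge(str(a), str(b), k_fast=kf, k_slow=ks, weight=kf / (kf + ks),
                   z=two_proportion_z(kf, nf, ks, ns))
    nx.write_graphml(g, str(path))
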