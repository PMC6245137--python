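"""Network construction, the two-proportion Z test, and significance pruning."""

import itertools

import numpy as np
import pytest

import diabnet as dn
from diabnet.features import FeatureToken
from diabnet.network import element_key, z_critical

A = FeatureToken("diagnosis", "A00", "present")
B = FeatureToken("diagnosis", "B00", "present")
C = FeatureToken("diagnosis", "C00", "present")


# --- build_network ----------------------------------------------------------

def test_single_fast_patient_clique():
    net = dn.build_network({1: frozenset({A, B})}, {1: "fast"})
    assert net.node_counts == {A: (1, 0), B: (1, 0)}
    assert net.edge_counts == {(A, B): (1, 0)}
    assert net.stats(A, 0.0).weight == 1.0
    assert net.stats((A, B), 0.0).weight == 1.0


def test_two_patient_hand_count():
    net = dn.build_network(
        {1: frozenset({A, B}), 2: frozenset({A})}, {1: "fast", 2: "slow"}
    )
    assert net.stats(A, 0.0).weight == 0.5
    assert net.stats(B, 0.0).weight == 1.0
    assert net.stats((A, B), 0.0).weight == 1.0


def test_clique_size_edges():
    tokens = frozenset(FeatureToken("diagnosis", f"D{i:02d}", "present") for i in range(7))
    net = dn.build_network({1: tokens, 2: frozenset({A})}, {1: "fast", 2: "slow"})
    assert len(net.edge_counts) == 7 * 6 // 2
    assert all(v == (1, 0) for v in net.edge_counts.values())


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        dn.build_network({}, {})
    with pytest.raises(ValueError):
        dn.build_network({1: frozenset({A})}, {1: "unlabeled"})


def test_counters_match_brute_force_enumeration():
    """On small cohorts the incidence-matrix path equals direct enumeration."""
    rng = np.random.default_rng(17)
    pool = [FeatureToken("diagnosis", f"D{i:02d}", "present") for i in range(8)]
    for _ in range(10):
        n = int(rng.integers(2, 21))
        labels = {}
        sets = {}
        for i in range(n):
            labels[i] = "fast" if (rng.random() < 0.5 or i == 0) else "slow"
            sets[i] = frozenset(t for t in pool if rng.random() < 0.4)
        labels[n - 1] = "slow"
        net = dn.build_network(sets, labels)
        # brute force
        nodes, edges = {}, {}
        for i in range(n):
            g = 0 if labels[i] == "fast" else 1
            for t in sets[i]:
                nodes.setdefault(t, [0, 0])[g] += 1
            for a, b in itertools.combinations(sorted(sets[i]), 2):
                edges.setdefault((a, b), [0, 0])[g] += 1
        assert net.node_counts == {t: tuple(v) for t, v in nodes.items()}
        assert net.edge_counts == {e: tuple(v) for e, v in edges.items()}


def test_counter_conservation(planted_cohort):
    """k_fast + k_slow of a node equals its total carrier count."""
    patients, dx, clinical, truth = planted_cohort
    labels = dict(zip(truth["STUDYID"], truth["LABEL"]))
    ev, _ = dn.window_features(dx, None, complication="kidney")
    sets = dn.tokenize_cohort(patients, ev, None, {}, status_rules={})
    net = dn.build_network(sets, labels)
    for token, (kf, ks) in net.node_counts.items():
        carriers = sum(token in s for s in sets.values())
        assert kf + ks == carriers
    for (a, b), (kf, ks) in list(net.edge_counts.items())[:200]:
        assert kf <= net.node_counts[a][0] and kf <= net.node_counts[b][0]
        assert ks <= net.node_counts[a][1] and ks <= net.node_counts[b][1]


# --- two_proportion_z -------------------------------------------------------

def test_z_hand_computed_value():
    # pooled p=0.7, se=sqrt(0.7*0.3*(1/100+1/100)), z=(0.8-0.6)/se
    assert dn.two_proportion_z(80, 100, 60, 100) == pytest.approx(3.0860670, abs=1e-6)


def test_z_equal_proportions_zero():
    assert dn.two_proportion_z(30, 100, 15, 50) == 0.0


def test_z_degenerate_pool_zero():
    assert dn.two_proportion_z(0, 50, 0, 50) == 0.0
    assert dn.two_proportion_z(50, 50, 50, 50) == 0.0


def test_z_domain_errors():
    with pytest.raises(ValueError):
        dn.two_proportion_z(1, 0, 1, 10)
    with pytest.raises(ValueError):
        dn.two_proportion_z(11, 10, 1, 10)


def test_z_matches_pooled_closed_form_on_random_tuples():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n1, n2 = int(rng.integers(1, 500)), int(rng.integers(1, 500))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        p = (k1 + k2) / (n1 + n2)
        expected = 0.0 if p in (0.0, 1.0) else (
            (k1 / n1 - k2 / n2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        )
        assert dn.two_proportion_z(k1, n1, k2, n2) == pytest.approx(expected, abs=1e-10)


# --- prune ------------------------------------------------------------------

def _net_from_counts(node_counts, n_fast, n_slow):
    return dn.HeteroNetwork(n_fast, n_slow, dict(node_counts), {})


def test_prune_threshold_behaviour():
    # |z| below 1.96 removed, above kept
    net = _net_from_counts({A: (110, 100), B: (140, 100)}, 200, 200)
    zA = abs(dn.two_proportion_z(110, 200, 100, 200))
    zB = abs(dn.two_proportion_z(140, 200, 100, 200))
    assert zA < 1.96 < zB  # sanity of the fixture
    pruned = dn.prune(net, alpha=0.05)
    assert A not in pruned.node_counts and B in pruned.node_counts


def test_prune_alpha_one_keeps_everything():
    net = _net_from_counts({A: (1, 1), B: (5, 4)}, 10, 10)
    pruned = dn.prune(net, alpha=1.0)
    assert set(pruned.node_counts) == {A, B}


def test_prune_monotone_in_alpha():
    rng = np.random.default_rng(5)
    counts = {
        FeatureToken("diagnosis", f"D{i:02d}", "present"):
            (int(rng.integers(0, 101)), int(rng.integers(0, 101)))
        for i in range(50)
    }
    counts = {t: c for t, c in counts.items() if sum(c) > 0}
    net = _net_from_counts(counts, 100, 100)
    prev = None
    for alpha in (0.2, 0.1, 0.05, 0.01):
        surv = set(dn.prune(net, alpha).node_counts)
        if prev is not None:
            assert surv <= prev
        prev = surv


def test_null_survival_fraction_near_alpha():
    """Type-I control: uninformative tokens survive pruning at ~alpha rate."""
    rng = np.random.default_rng(31)
    n = 800
    labels = {i: ("fast" if i < n // 2 else "slow") for i in range(n)}
    pool = [FeatureToken("diagnosis", f"D{i:03d}", "present") for i in range(150)]
    sets = {i: frozenset(t for t in pool if rng.random() < 0.3) for i in range(n)}
    net = dn.build_network(sets, labels)
    pruned = dn.prune(net, 0.05)
    frac = len(pruned.node_counts) / len(net.node_counts)
    se = np.sqrt(0.05 * 0.95 / 150)
    assert abs(frac - 0.05) <= 3 * se


# --- top_conditions ---------------------------------------------------------

def test_top_by_weight():
    net = _net_from_counts({A: (9, 1), B: (8, 2)}, 10, 10)
    by_w, _ = dn.top_conditions(net, 1, z_crit=0.0)
    assert by_w[0].element == A


def test_top_ties_break_lexicographically():
    net = _net_from_counts({B: (5, 5), A: (5, 5), C: (5, 5)}, 10, 10)
    by_w, by_z = dn.top_conditions(net, 3, z_crit=0.0)
    assert [s.element for s in by_w] == [A, B, C]
    assert [s.element for s in by_z] == [A, B, C]


def test_top_m_nonpositive_empty():
    net = _net_from_counts({A: (1, 0)}, 1, 1)
    assert dn.top_conditions(net, 0) == ([], [])


def test_planted_token_ranks_first_by_z():
    """A strongly planted feature tops the Z ranking of the pruned network."""
    cfg = dn.SyntheticCohortConfig(
        n_patients=2000, planted=[dn.PlantedFeature("F00", 0.9, 0.3)], seed=13
    )
    patients, dx, clinical, truth = dn.generate_cohort(cfg)
    labels = dict(zip(truth["STUDYID"], truth["LABEL"]))
    ev, _ = dn.window_features(dx, None, complication="kidney")
    sets = dn.tokenize_cohort(patients, ev, None, {}, status_rules={})
    net = dn.build_network(sets, labels)
    pruned = dn.prune(net, 0.05)
    _, by_z = dn.top_conditions(pruned, 1)
    assert by_z[0].element == FeatureToken("diagnosis", "F00", "present")


def test_write_network_roundtrip_columns(tmp_path):
    net = dn.build_network(
        {1: frozenset({A, B}), 2: frozenset({A})}, {1: "fast", 2: "slow"}
    )
    paths = dn.write_network(net, tmp_path)
    import pandas as pd

    nodes = pd.read_csv(paths["nodes"])
    edges = pd.read_csv(paths["edges"])
    assert list(nodes.columns) == ["KIND", "NAME", "LEVEL", "K_FAST", "K_SLOW",
                                   "WEIGHT", "Z"]
    assert len(nodes) == 2 and len(edges) == 1
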