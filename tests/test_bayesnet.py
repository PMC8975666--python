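"""MMHC structure learning: dependence statistic, skeleton, search, inference."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prognet import bayesnet, synthetic
from prognet.bayesnet import (
    DiscreteBayesianNetwork,
    assoc,
    build_skeleton,
    cpdag,
    fit_parameters,
    hill_climb,
    min_assoc,
    mmpc,
    predict_outcome,
    shd_cpdag,
    structural_hamming_distance,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def g2_oracle(data: pd.DataFrame, x: str, t: str, z: tuple[str, ...]) -> float:
    """Naive cell-sum evaluation of the conditional G² statistic."""
    stat = 0.0
    lv = {c: sorted(data[c].unique()) for c in (x, t, *z)}
    for zc in itertools.product(*(lv[c] for c in z)) if z else [()]:
        sub = data
        for c, val in zip(z, zc):
            sub = sub[sub[c] == val]
        n_c = len(sub)
        for a in lv[x]:
            for b in lv[t]:
                n_abc = len(sub[(sub[x] == a) & (sub[t] == b)])
                n_ac = len(sub[sub[x] == a])
                n_bc = len(sub[sub[t] == b])
                if n_abc > 0:
                    stat += 2 * n_abc * math.log(n_abc * n_c / (n_ac * n_bc))
    return stat


def joint_posterior_oracle(net: DiscreteBayesianNetwork, evidence: dict,
                           target: str) -> np.ndarray:
    """Posterior from an explicitly materialized full joint table."""
    names = net.nodes
    shape = tuple(net.levels[v] for v in names)
    joint = np.zeros(shape)
    for cfg in itertools.product(*(range(k) for k in shape)):
        assign = dict(zip(names, cfg))
        p = 1.0
        for v in names:
            idx = tuple(assign[q] for q in net.parents[v]) + (assign[v],)
            p *= net.cpts[v][idx]
        joint[cfg] = p
    for v, val in evidence.items():
        sl = [slice(None)] * len(names)
        keep = np.zeros(net.levels[v], dtype=bool)
        keep[val] = True
        sl[names.index(v)] = keep
        mask = np.zeros(shape)
        mask[tuple(sl)] = 1.0
        joint = joint * mask
    axes = tuple(i for i, v in enumerate(names) if v != target)
    post = joint.sum(axis=axes)
    return post / post.sum()


def random_network(rng: np.random.Generator, n_nodes: int) -> DiscreteBayesianNetwork:
    names = [f"v{i}" for i in range(n_nodes)]
    levels = {v: int(rng.integers(2, 4)) for v in names}
    parents = {}
    for i, v in enumerate(names):
        pool = names[:i]
        k = int(rng.integers(0, min(2, len(pool)) + 1))
        parents[v] = tuple(sorted(rng.choice(pool, size=k, replace=False))) if k else ()
    cpts = {}
    for v in names:
        shape = tuple(levels[p] for p in parents[v]) + (levels[v],)
        raw = rng.gamma(1.0, 1.0, size=shape) + 0.05
        cpts[v] = raw / raw.sum(axis=-1, keepdims=True)
    return DiscreteBayesianNetwork(names, levels, parents, cpts)


def random_discrete_frame(rng, n_rows, cols, levels=3) -> pd.DataFrame:
    return pd.DataFrame({c: rng.integers(0, levels, n_rows) for c in cols})


# ---------------------------------------------------------------------------
# Assoc / MinAssoc
# ---------------------------------------------------------------------------

class TestAssoc:
    def test_identical_variables_closed_form(self):
        x = np.repeat([0, 1], 50)
        df = pd.DataFrame({"x": x, "t": x})
        res = assoc(df, "x", "t")
        assert res.statistic == pytest.approx(2 * 100 * np.log(2), rel=1e-12)
        assert res.df == 1

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            df = random_discrete_frame(rng, 200, ["x", "t", "z1", "z2"])
            for z in [(), ("z1",), ("z1", "z2")]:
                res = assoc(df, "x", "t", z)
                assert res.statistic == pytest.approx(
                    g2_oracle(df, "x", "t", z), rel=1e-9, abs=1e-9)

    def test_exact_independence_gives_zero(self):
        # counts with N_ab · N = N_a · N_b in every cell
        rows = ([(0, 0)] * 4 + [(0, 1)] * 6 + [(1, 0)] * 6 + [(1, 1)] * 9)
        df = pd.DataFrame(rows, columns=["x", "t"])
        assert assoc(df, "x", "t").statistic == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(5):
            df = random_discrete_frame(rng, 150, ["x", "t", "z"])
            a = assoc(df, "x", "t", ("z",))
            b = assoc(df, "t", "x", ("z",))
            assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
            assert a.statistic >= 0.0
            assert 0.0 <= a.p_value <= 1.0

    def test_overlapping_variables_rejected(self, rng):
        df = random_discrete_frame(rng, 50, ["x", "t"])
        with pytest.raises(ValueError):
            assoc(df, "x", "x")

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            assoc(pd.DataFrame({"x": [], "t": []}), "x", "t")


class TestMinAssoc:
    def test_empty_conditioning_set_is_plain_assoc(self, rng):
        df = random_discrete_frame(rng, 100, ["x", "t"])
        res, s = min_assoc(df, "x", "t", ())
        assert s == ()
        assert res.statistic == assoc(df, "x", "t").statistic

    def test_chain_minimizer_is_the_mediator(self):
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.integers(0, 2, n)
        w = np.where(rng.random(n) < 0.9, x, 1 - x)
        t = np.where(rng.random(n) < 0.9, w, 1 - w)
        df = pd.DataFrame({"x": x, "w": w, "t": t})
        res, s = min_assoc(df, "x", "t", ("w",))
        assert s == ("w",)
        assert res.p_value > 0.05

    def test_matches_subset_enumeration_oracle(self, rng):
        for _ in range(5):
            df = random_discrete_frame(rng, 200, ["x", "t", "a", "b", "c"], levels=2)
            res, s = min_assoc(df, "x", "t", ("a", "b", "c"), maxk=3)
            best_p, best_s = -1.0, None
            for size in range(4):
                for sub in itertools.combinations(("a", "b", "c"), size):
                    p = assoc(df, "x", "t", sub).p_value
                    if p > best_p:
                        best_p, best_s = p, sub
            assert res.p_value == pytest.approx(best_p, rel=1e-12)
            assert s == best_s


# ---------------------------------------------------------------------------
# MMPC
# ---------------------------------------------------------------------------

class TestMMPC:
    def test_null_model_type_one_behaviour(self):
        """Under mutual independence the per-candidate false-admission rate
        stays near the test level alpha (each pairwise test has exactly
        alpha type-I error, so with five candidates a seed has roughly a
        1 − 0.95⁵ ≈ 23% chance of any admission)."""
        admitted, empty = 0, 0
        n_seeds, n_candidates = 20, 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = random_discrete_frame(rng, 2000, [f"v{i}" for i in range(6)],
                                       levels=2)
            cpc = mmpc("v0", df)
            admitted += len(cpc.members)
            empty += len(cpc.members) == 0
        rate = admitted / (n_seeds * n_candidates)
        assert rate < 3 * 0.05
        assert empty >= n_seeds // 2

    def test_collider_recovery(self):
        # noisy-OR collider: marginally and conditionally dependent parents
        rng = np.random.default_rng(5)
        n = 5000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        p = 0.05 + 0.45 * a + 0.45 * b
        t = (rng.random(n) < p).astype(int)
        c = rng.integers(0, 2, n)
        df = pd.DataFrame({"a": a, "b": b, "t": t, "c": c})
        cpc = mmpc("t", df)
        assert set(cpc.members) == {"a", "b"}

    def test_single_variable_dataset(self):
        df = pd.DataFrame({"t": [0, 1] * 20})
        assert mmpc("t", df).members == ()

    def test_outcome_parent_set_on_default_truth(self, default_truth, cohort5000):
        cpc = mmpc("survival_status", cohort5000)
        expected = set(default_truth.network.parents["survival_status"])
        assert set(cpc.members) == expected

    def test_column_order_invariance(self, cohort5000):
        reversed_cols = cohort5000[list(cohort5000.columns)[::-1]]
        a = mmpc("survival_status", cohort5000)
        b = mmpc("survival_status", reversed_cols)
        assert set(a.members) == set(b.members)


# ---------------------------------------------------------------------------
# hill-climbing, parameters, inference
# ---------------------------------------------------------------------------

class TestHillClimb:
    def test_empty_skeleton_returns_empty_graph(self, rng):
        df = random_discrete_frame(rng, 100, ["a", "b"], levels=2)
        skel = nx.Graph()
        skel.add_nodes_from(["a", "b"])
        res = hill_climb(skel, df)
        assert res.graph.number_of_edges() == 0
        expected = sum(bayesnet.family_score(df, v, (), {"a": 2, "b": 2})
                       for v in ("a", "b"))
        assert res.score == pytest.approx(expected)

    def test_vstructure_recovery(self):
        rng = np.random.default_rng(9)
        n = 5000
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        t = (rng.random(n) < 0.05 + 0.45 * a + 0.45 * b).astype(int)
        df = pd.DataFrame({"a": a, "b": b, "t": t})
        skel = nx.Graph([("a", "t"), ("b", "t")])
        res = hill_climb(skel, df)
        truth = nx.DiGraph([("a", "t"), ("b", "t")])
        assert shd_cpdag(res.graph, truth) <= 1

    def test_every_accepted_move_strictly_improves(self, cohort5000):
        skel = build_skeleton(cohort5000)
        res = hill_climb(skel, cohort5000)
        assert all(delta > 0 for *_, delta in res.moves)
        assert nx.is_directed_acyclic_graph(res.graph)

    def test_final_score_at_least_empty_graph(self, cohort5000):
        skel = build_skeleton(cohort5000)
        res = hill_climb(skel, cohort5000)
        levels = {c: 2 for c in cohort5000.columns}
        empty = sum(bayesnet.family_score(cohort5000, v, (), levels)
                    for v in cohort5000.columns)
        assert res.score >= empty


class TestFitParameters:
    def test_single_node_mle(self):
        df = pd.DataFrame({"a": [1] * 30 + [0] * 70})
        g = nx.DiGraph()
        g.add_node("a")
        net = fit_parameters(g, df, pseudocount=0.0)
        assert net.cpts["a"][1] == pytest.approx(0.3)

    def test_smoothing_fills_unseen_configuration(self):
        df = pd.DataFrame({"p": [0] * 50, "c": [0, 1] * 25})
        net = fit_parameters(nx.DiGraph([("p", "c")]), df, pseudocount=1.0,
                             levels={"p": 2, "c": 2})
        np.testing.assert_allclose(net.cpts["c"][1], [0.5, 0.5])

    def test_consistency_at_large_n(self):
        """Fitted CPT rows converge to the truth when every parent
        configuration receives thousands of samples (a four-node net; the
        default truth's 64-row outcome table would leave rows too sparse
        at this n for such a bound)."""
        truth = synthetic.make_ground_truth({
            "nodes": {"a": 2, "b": 2, "t": 2, "d": 2},
            "edges": [("a", "t"), ("b", "t")],
            "cpts": {"a": [0.4, 0.6], "b": [0.7, 0.3], "d": [0.5, 0.5],
                     "t": [[[0.9, 0.1], [0.4, 0.6]],
                           [[0.3, 0.7], [0.15, 0.85]]]},
            "outcome": "t"})
        data = synthetic.sample_cohort(truth, 10_000, seed=12)
        net = fit_parameters(truth.network.graph(), data, pseudocount=1.0)
        for v in net.nodes:
            err = np.abs(net.cpts[v] - truth.network.cpts[v]).max()
            assert err < 0.05

    def test_missing_node_rejected(self):
        df = pd.DataFrame({"a": [0, 1]})
        with pytest.raises(ValueError, match="absent"):
            fit_parameters(nx.DiGraph([("a", "b")]), df)


class TestInference:
    def test_single_node_marginal(self):
        net = DiscreteBayesianNetwork(["a"], {"a": 3}, {"a": ()},
                                      {"a": np.array([0.2, 0.3, 0.5])})
        res = predict_outcome(net, {}, target="a")
        np.testing.assert_allclose(res["posterior"], [0.2, 0.3, 0.5])

    def test_full_parent_evidence_reads_cpt_row(self, default_truth):
        net = default_truth.network
        ev = {p: 1 for p in net.parents["survival_status"]}
        res = predict_outcome(net, ev, target="survival_status")
        np.testing.assert_allclose(res["posterior"],
                                   net.cpts["survival_status"][(1,) * 6],
                                   atol=1e-12)

    def test_matches_full_joint_oracle(self, rng):
        for _ in range(8):
            net = random_network(rng, 5)
            observed = [v for v in net.nodes[:-1] if rng.random() < 0.5]
            evidence = {v: int(rng.integers(net.levels[v])) for v in observed}
            target = net.nodes[-1]
            got = predict_outcome(net, evidence, target=target)["posterior"]
            want = joint_posterior_oracle(net, evidence, target)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_invalid_evidence_value(self, default_truth):
        with pytest.raises(ValueError, match="outside"):
            predict_outcome(default_truth.network, {"tumor_stage": 5},
                            target="survival_status")


class TestGraphDistance:
    def test_identical_graphs(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        assert structural_hamming_distance(g, g) == 0

    def test_single_reversal_costs_one(self):
        g1 = nx.DiGraph([("a", "b")])
        g2 = nx.DiGraph([("b", "a")])
        assert structural_hamming_distance(g1, g2) == 1

    def test_matches_pairwise_edit_oracle(self, rng):
        nodes = ["a", "b", "c", "d"]
        for _ in range(20):
            def rand_dag():
                g = nx.DiGraph()
                g.add_nodes_from(nodes)
                for i, u in enumerate(nodes):
                    for v in nodes[i + 1:]:
                        r = rng.random()
                        if r < 0.3:
                            g.add_edge(u, v)
                        elif r < 0.5:
                            g.add_edge(v, u)
                return g
            g1, g2 = rand_dag(), rand_dag()
            edits = 0
            for u, v in itertools.combinations(nodes, 2):
                s1 = (g1.has_edge(u, v), g1.has_edge(v, u))
                s2 = (g2.has_edge(u, v), g2.has_edge(v, u))
                edits += s1 != s2
            assert structural_hamming_distance(g1, g2) == edits

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structural_hamming_distance(nx.DiGraph([("a", "b")]),
                                        nx.DiGraph([("a", "c")]))

    def test_cpdag_of_default_truth(self, default_truth):
        directed, undirected = cpdag(default_truth.network.graph())
        # the six collider edges into the outcome are compelled …
        assert all((p, "survival_status") in directed
                   for p in default_truth.network.parents["survival_status"])
        # … and the shielded stage→positive-nodes edge is reversible
        assert frozenset(("tumor_stage", "positive_lymph_nodes")) in undirected


def test_network_text_roundtrip(default_truth):
    net = default_truth.network
    back = DiscreteBayesianNetwork.from_text(net.to_text())
    assert back.nodes == net.nodes
    assert back.parents == net.parents
    assert back.outcome == net.outcome
    for v in net.nodes:
        np.testing.assert_allclose(back.cpts[v], net.cpts[v], atol=1e-12)


def test_full_mmhc_recovery_and_prediction(default_truth, cohort5000):
    """MMHC on the default truth recovers the equivalence class and the
    fitted network predicts survival better than the majority class."""
    net, hc = bayesnet.mmhc(cohort5000, outcome="survival_status")
    assert shd_cpdag(net.graph(), default_truth.network.graph()) <= 2
    test = synthetic.sample_cohort(default_truth, 1000, seed=99,
                                   continuous=False)
    correct = 0
    evidence_vars = [v for v in net.nodes if v != "survival_status"]
    for _, row in test.iterrows():
        res = predict_outcome(net, {v: int(row[v]) for v in evidence_vars},
                              target="survival_status")
        correct += res["level"] == row["survival_status"]
    accuracy = correct / len(test)
    majority = max(test["survival_status"].mean(),
                   1 - test["survival_status"].mean())
    assert accuracy > majority
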