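"""Co-occurrence network construction, modules, Zi-Pi and keystones.

Oracles: scipy's spearmanr and a hand-rolled rank-then-Pearson for the
correlation routine; brute-force double loops for the edge predicate and the
Zi/Pi definitions; exhaustive modularity maximization on a small graph for
module detection; planted-structure simulations for recovery.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import rarenet as rn
from rarenet._stats import spearman_rho_p, spearman_matrix, pvalue_from_rho


def oracle_spearman(x, y):
    """Independent oracle: average ranks, Pearson, two-sided t approximation."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, 2 * sps.t.sf(abs(t), n - 2)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_rho_p(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rho_p(x, -np.exp(x))[0] == pytest.approx(-1.0)
        assert spearman_rho_p(x, x**3)[1] == 0.0

    def test_tied_example_matches_oracle(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        rho, p = spearman_rho_p(x, y)
        orho, op = oracle_spearman(x, y)
        assert rho == pytest.approx(orho, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)
        # scipy agrees too
        sci = sps.spearmanr(x, y)
        assert rho == pytest.approx(float(sci.statistic), abs=1e-12)

    def test_random_pairs_match_oracle_including_ties(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(5, 40)
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            rho, p = spearman_rho_p(x, y)
            orho, op = oracle_spearman(x, y)
            if np.isnan(rho):
                assert np.std(sps.rankdata(x)) == 0
                continue
            assert rho == pytest.approx(orho, abs=1e-12)
            assert p == pytest.approx(op, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman_rho_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(4, size=(12, 9)).astype(float)
        rho, p = spearman_matrix(x)
        assert np.allclose(rho, rho.T, atol=1e-12)
        for i, j in itertools.combinations(range(12), 2):
            er, ep = spearman_rho_p(x[i], x[j])
            if np.isnan(er):
                assert np.isnan(rho[i, j])
            else:
                assert rho[i, j] == pytest.approx(er, abs=1e-12)
                assert p[i, j] == pytest.approx(ep, abs=1e-12)


class TestPrevalenceFilter:
    def _table(self, present_counts, n_samples=34):
        rows = []
        for k in present_counts:
            row = [1] * k + [0] * (n_samples - k)
            rows.append(row)
        frame = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))],
                             columns=[f"s{j}" for j in range(n_samples)])
        return rn.AsvTable(frame)

    def test_strictly_more_than_half(self):
        table = self._table([17, 18, 34])
        got = rn.prevalence_filter(table, 0.5)
        assert got.asv_ids == ["t1", "t2"]  # 17/34 is not "more than 50%"

    def test_zero_fraction_drops_only_absent(self):
        table = self._table([0, 1, 34])
        got = rn.prevalence_filter(table, 0.0)
        assert got.asv_ids == ["t1", "t2"]


class TestBuildNetwork:
    def _corr(self, rho, p, labels):
        idx = pd.Index(labels)
        return rn.CorrelationMatrix(pd.DataFrame(rho, index=idx, columns=idx),
                                    pd.DataFrame(p, index=idx, columns=idx))

    def test_threshold_is_strict(self):
        rho = np.array([[1.0, 0.6], [0.6, 1.0]])
        p = np.array([[0.0, 1e-9], [1e-9, 0.0]])
        g = rn.build_network(self._corr(rho, p, ["a", "b"]))
        assert g.number_of_edges() == 0

    def test_negative_edge_sign(self):
        rho = np.array([[1.0, -0.9], [-0.9, 1.0]])
        p = np.array([[0.0, 1e-6], [1e-6, 0.0]])
        g = rn.build_network(self._corr(rho, p, ["a", "b"]))
        assert g.edges[("a", "b")]["sign"] == "negative"

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(77)
        n = 120
        x = rng.normal(size=(n, 20))
        rho, p = spearman_matrix(x)
        labels = [f"t{i}" for i in range(n)]
        g = rn.build_network(rn.CorrelationMatrix(
            pd.DataFrame(rho, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels)))
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                if abs(rho[i, j]) > 0.6 and p[i, j] < 0.05:
                    expected.add(frozenset((labels[i], labels[j])))
        got = {frozenset(e) for e in g.edges}
        assert got == expected


def _set_partitions(items):
    """All partitions of a list into non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for i, block in enumerate(partial):
            yield partial[:i] + [[first] + block] + partial[i + 1:]
        yield [[first]] + partial


class TestDetectModules:
    def test_two_cliques_match_exhaustive_modularity_oracle(self):
        # two 4-cliques joined by one edge: exhaustive search over all
        # 4140 partitions confirms the clique split maximizes modularity
        g = nx.Graph()
        a = [f"a{i}" for i in range(4)]
        b = [f"b{i}" for i in range(4)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edge(a[0], b[0])
        best, best_q = None, -np.inf
        for partition in _set_partitions(list(g.nodes)):
            q = nx.algorithms.community.modularity(g, [set(p) for p in partition])
            if q > best_q:
                best, best_q = partition, q
        assert sorted(map(sorted, best)) == sorted(map(sorted, [a, b]))
        modules = rn.detect_modules(g, seed=0)
        assert len(set(modules.values())) == 2
        assert len({modules[v] for v in a}) == 1
        assert len({modules[v] for v in b}) == 1

    def test_two_five_cliques(self):
        g = nx.Graph()
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edge(a[0], b[0])
        modules = rn.detect_modules(g, seed=1)
        assert {modules[v] for v in a} != {modules[v] for v in b}
        assert len(set(modules.values())) == 2

    def test_single_clique_one_module(self):
        g = nx.complete_graph(6)
        modules = rn.detect_modules(g, seed=0)
        assert set(modules.values()) == {1}

    def test_deterministic_given_seed(self):
        g, _ = rn.planted_partition_graph(3, 20, 0.5, 0.05, seed=9)
        assert rn.detect_modules(g, seed=4) == rn.detect_modules(g, seed=4)

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rn.detect_modules(nx.Graph(), seed=0)

    def test_planted_partition_recovery(self):
        aris = []
        for seed in range(10):
            g, truth = rn.planted_partition_graph(4, 30, 0.6, 0.02, seed=seed)
            modules = rn.detect_modules(g, seed=seed)
            nodes = list(g.nodes)
            aris.append(adjusted_rand_score(
                [truth[v] for v in nodes], [modules[v] for v in nodes]))
        assert np.mean(aris) >= 0.9


def oracle_zi_pi(g, modules):
    """Direct-definition recomputation of Zi and Pi."""
    out = {}
    all_mods = set(modules.values())
    within = {
        v: sum(1 for u in g.neighbors(v) if modules[u] == modules[v]) for v in g.nodes
    }
    for v in g.nodes:
        k = g.degree(v)
        member_within = [within[u] for u in g.nodes if modules[u] == modules[v]]
        sd = np.std(member_within)
        zi = 0.0 if sd == 0 else (within[v] - np.mean(member_within)) / sd
        pi = 1.0
        for s in all_mods:
            k_is = sum(1 for u in g.neighbors(v) if modules[u] == s)
            pi -= (k_is / k) ** 2
        out[v] = (zi, pi)
    return out


class TestZiPi:
    def test_all_internal_links_give_zero_pi(self):
        g = nx.complete_graph(5)
        modules = {v: 1 for v in g.nodes}
        zipi = rn.zi_pi(g, modules)
        assert np.allclose(zipi["Pi"], 0.0)

    def test_even_split_over_two_modules(self):
        g = nx.star_graph(4)  # hub 0 with leaves 1..4
        modules = {0: 1, 1: 1, 2: 1, 3: 2, 4: 2}
        zipi = rn.zi_pi(g, modules)
        assert zipi.loc[0, "Pi"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(50, 0.12, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules = {v: int(rng.integers(1, 5)) for v in g.nodes}
        zipi = rn.zi_pi(g, modules)
        expect = oracle_zi_pi(g, modules)
        for v in g.nodes:
            assert zipi.loc[v, "Zi"] == pytest.approx(expect[v][0], abs=1e-12)
            assert zipi.loc[v, "Pi"] == pytest.approx(expect[v][1], abs=1e-12)

    def test_degree_conservation_and_pi_bound(self):
        g = nx.gnp_random_graph(80, 0.08, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        modules = rn.detect_modules(g, seed=0)
        n_mods = len(set(modules.values()))
        zipi = rn.zi_pi(g, modules)
        for v in g.nodes:
            k_total = sum(1 for _ in g.neighbors(v))
            assert zipi.loc[v, "degree"] == k_total
        assert (zipi["Pi"] >= -1e-12).all()
        assert (zipi["Pi"] <= 1 - 1 / n_mods + 1e-12).all()


class TestRolesAndKeystones:
    @pytest.mark.parametrize("zi, pi, role", [
        (3.0, 0.1, "module hub"),
        (0.2, 0.7, "connector"),
        (3.0, 0.7, "network hub"),
        (0.2, 0.1, "peripheral"),
        (2.5, 0.62, "peripheral"),  # boundary goes to the lower class
    ])
    def test_role_rules(self, zi, pi, role):
        zipi = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["x"])
        assert rn.classify_roles(zipi)["x"] == role

    def test_keystones_are_non_peripherals(self):
        zipi = pd.DataFrame({"Zi": [3.0, 0.0, 0.1], "Pi": [0.1, 0.7, 0.0]},
                            index=["hub", "conn", "per"])
        roles = rn.classify_roles(zipi)
        assert rn.keystone_set(roles) == {"hub", "conn"}
        assert rn.keystone_set(pd.Series({"a": "peripheral"})) == set()

    def test_planted_keystone_recovery(self):
        recalls, conn_pis = [], []
        for seed in range(8):
            g, truth = rn.planted_role_graph(seed=seed)
            modules = rn.detect_modules(g, seed=seed)
            zipi = rn.zi_pi(g, modules)
            roles = rn.classify_roles(zipi)
            keystones = rn.keystone_set(roles)
            planted = set(truth["hubs"]) | set(truth["connectors"])
            recalls.append(len(keystones & planted) / len(planted))
            conn_pis.extend(zipi.loc[truth["connectors"], "Pi"])
        assert np.mean(recalls) >= 0.8
        assert np.allclose(conn_pis, 0.75, atol=0.1)


class TestNetworkSummary:
    def test_all_positive_toy_network(self):
        rho = np.array([
            [1.0, 0.9, 0.8],
            [0.9, 1.0, 0.85],
            [0.8, 0.85, 1.0],
        ])
        p = np.full((3, 3), 1e-6)
        np.fill_diagonal(p, 0.0)
        labels = ["a", "b", "c"]
        g = rn.build_network(rn.CorrelationMatrix(
            pd.DataFrame(rho, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels)))
        modules = rn.detect_modules(g, seed=0)
        roles = rn.classify_roles(rn.zi_pi(g, modules))
        summary = rn.network_summary(g, modules, roles)
        assert summary["n_nodes"] == 3 and summary["n_edges"] == 3
        assert summary["pct_positive_edges"] == 100.0
        assert summary["pct_negative_edges"] == 0.0

    def test_edge_percentages_sum_to_100(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(size=16) for _ in range(30)])
        x[1] = x[0] + 0.01 * rng.normal(size=16)
        x[2] = -x[0] + 0.01 * rng.normal(size=16)
        rho, p = spearman_matrix(x)
        labels = [f"t{i}" for i in range(30)]
        g = rn.build_network(rn.CorrelationMatrix(
            pd.DataFrame(rho, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels)))
        modules = rn.detect_modules(g, seed=0)
        roles = rn.classify_roles(rn.zi_pi(g, modules))
        summary = rn.network_summary(g, modules, roles)
        assert summary["pct_positive_edges"] + summary["pct_negative_edges"] == pytest.approx(100.0)
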