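"""Co-occurrence networks, network comparison, and correlation panels."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from conftest import brute_force_bh
from gutosi.networks import (compare_networks, cooccurrence_network,
                             feature_phenotype_correlations, harmonic_closeness)


def _table(cols: dict) -> pd.DataFrame:
    df = pd.DataFrame(cols)
    df.index = [f"s{i}" for i in range(len(df))]
    return df


class TestCooccurrenceNetwork:
    def test_perfect_concordance_is_retained(self):
        x = np.arange(9, dtype=float)
        table = _table({"a": x, "b": np.exp(x)})  # monotone together
        net = cooccurrence_network(table)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["rho"] == pytest.approx(1.0)
        assert net.edges.iloc[0]["sign"] == 1

    def test_rho_matches_rank_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=9), rng.normal(size=9)
        table = _table({"a": x, "b": y})
        net = cooccurrence_network(table, rho_min=0.0, alpha=1.0)
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert net.edges.iloc[0]["rho"] == pytest.approx(expected, abs=1e-12)

    def test_independent_taxa_rarely_pass_the_dual_threshold(self):
        """Null retention is far below alpha: with ~1000 independent
        pairs, the dual threshold (BH-adjusted p AND |rho| > 0.7) keeps
        essentially nothing."""
        rng = np.random.default_rng(1)
        table = _table({f"t{i}": rng.normal(size=10) for i in range(46)})
        net = cooccurrence_network(table)  # 1035 pairs
        n_pairs = 46 * 45 // 2
        assert len(net.edges) / n_pairs < 0.005

    def test_constant_taxon_excluded(self):
        table = _table({"a": np.arange(6, dtype=float),
                        "b": np.arange(6, dtype=float)[::-1],
                        "flat": np.ones(6)})
        net = cooccurrence_network(table)
        assert net.excluded == ["flat"]
        assert "flat" not in net.graph

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError):
            cooccurrence_network(_table({"a": [1.0, 2], "b": [2.0, 1]}))


class TestCompareNetworks:
    def _net(self, edges, seed=0, n=9):
        """Build a network whose retained edges are exactly `edges`
        (pairs with sign) by planting perfect monotone relationships."""
        rng = np.random.default_rng(seed)
        x = np.arange(n, dtype=float)
        cols = {}
        nodes = sorted({v for e in edges for v in e[:2]})
        for i, node in enumerate(nodes):
            cols[node] = rng.normal(size=n)
        for a, b, sign in edges:
            cols[b] = cols[a] * sign + 0.0
        return cooccurrence_network(_table(cols))

    def test_self_comparison_shares_everything(self):
        net = self._net([("a", "b", 1), ("c", "d", -1)])
        cmp = compare_networks(net, net)
        assert cmp.unique_a == cmp.unique_b == 0
        assert len(cmp.shared_edges) == len(net.edges)

    def test_sign_flip_is_not_shared(self):
        pos = self._net([("a", "b", 1)], seed=1)
        neg = self._net([("a", "b", -1)], seed=1)
        cmp = compare_networks(pos, neg)
        assert len(cmp.shared_edges) == 0
        assert cmp.unique_a == 1 and cmp.unique_b == 1

    def test_shared_edges_symmetric(self):
        a = self._net([("a", "b", 1), ("b", "c", 1)], seed=2)
        b = self._net([("a", "b", 1), ("c", "d", -1)], seed=3)
        ab = compare_networks(a, b).shared_edges
        ba = compare_networks(b, a).shared_edges
        pd.testing.assert_frame_equal(ab, ba)

    def test_threshold_mismatch_is_an_error(self):
        net = self._net([("a", "b", 1)])
        other = self._net([("a", "b", 1)])
        other.rho_min = 0.5
        with pytest.raises(ValueError, match="threshold"):
            compare_networks(net, other)

    def test_empty_comparison_is_flagged(self):
        rng = np.random.default_rng(4)
        empty = cooccurrence_network(
            _table({"a": rng.normal(size=8), "b": rng.normal(size=8)}))
        assert len(empty.edges) == 0
        cmp = compare_networks(empty, empty)
        assert cmp.empty
        assert len(cmp.shared_edges) == 0


class TestHarmonicCloseness:
    def test_matches_brute_force_on_five_node_toy(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        G.add_node("e")  # disconnected
        result = harmonic_closeness(G)
        n = G.number_of_nodes()
        lengths = dict(nx.all_pairs_shortest_path_length(G))
        for v in G:
            expected = sum(
                1.0 / lengths[v][u] for u in G if u != v and u in lengths[v]
            ) / (n - 1)
            assert result[v] == pytest.approx(expected, abs=1e-12), v

    def test_defined_on_singletons(self):
        G = nx.Graph()
        G.add_node("a")
        assert harmonic_closeness(G) == {"a": 0.0}


class TestFeaturePhenotypeCorrelations:
    def test_feature_equal_to_target(self):
        target = pd.Series(np.arange(7, dtype=float), index=[f"s{i}" for i in range(7)])
        feats = pd.DataFrame({"same": target, "rev": target.iloc[::-1].to_numpy()},
                             index=target.index)
        panel = feature_phenotype_correlations(feats, target)
        assert panel.loc["same", "rho"] == pytest.approx(1.0)
        assert panel.loc["rev", "rho"] == pytest.approx(-1.0)
        assert panel.loc["same", "pvalue"] < 0.05

    def test_exact_p_matches_permutation_enumeration(self):
        rng = np.random.default_rng(5)
        n = 6
        x, y = rng.normal(size=n), rng.normal(size=n)
        feats = pd.DataFrame({"f": x}, index=[f"s{i}" for i in range(n)])
        target = pd.Series(y, index=feats.index)
        p_impl = feature_phenotype_correlations(feats, target).loc["f", "pvalue"]
        rx, ry = rankdata(x), rankdata(y)
        rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in permutations(rx):
            rho = abs(np.corrcoef(np.array(perm), ry)[0, 1])
            total += 1
            hits += rho >= rho_obs - 1e-12
        assert p_impl == pytest.approx(hits / total)

    def test_short_features_are_skipped(self):
        target = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                           index=[f"s{i}" for i in range(5)])
        feats = pd.DataFrame({"short": [1.0, 2.0, np.nan, np.nan, np.nan],
                              "ok": [5.0, 3.0, 1.0, 2.0, 4.0]}, index=target.index)
        panel = feature_phenotype_correlations(feats, target)
        assert "short" not in panel.index and "ok" in panel.index

    def test_stars_reflect_p_bands(self):
        target = pd.Series(np.arange(9, dtype=float), index=[f"s{i}" for i in range(9)])
        feats = pd.DataFrame({"same": target}, index=target.index)
        panel = feature_phenotype_correlations(feats, target)
        assert panel.loc["same", "stars"] == "***"


def test_bh_adjustment_matches_step_up_definition():
    """statsmodels BH (used for edge and feature p-values) agrees with the
    step-up procedure written from its definition, and never decreases p."""
    rng = np.random.default_rng(6)
    for _ in range(10):
        p = rng.uniform(size=rng.integers(2, 21))
        lib = multipletests(p, method="fdr_bh")[1]
        ref = brute_force_bh(p)
        assert np.allclose(lib, ref, atol=1e-12)
        assert (lib >= p - 1e-12).all()


def test_monotone_transform_invariance():
    """Rank-based networks are unchanged by monotone transforms."""
    rng = np.random.default_rng(7)
    table = _table({c: rng.lognormal(0, 1, 10) for c in "abcd"})
    base = cooccurrence_network(table, rho_min=0.0, alpha=1.0)
    transformed = table.copy()
    transformed["a"] = np.log(transformed["a"])
    transformed["b"] = transformed["b"] ** 3
    after = cooccurrence_network(transformed, rho_min=0.0, alpha=1.0)
    pd.testing.assert_frame_equal(base.edges, after.edges)
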