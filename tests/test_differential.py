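"""Kruskal-Wallis screen, LDA effect size, and Wilcoxon fold change."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gutosi.differential import (kruskal_wallis_screen, lda_effect_size, lefse,
                                 wilcoxon_fold_change)


def brute_force_kw(groups):
    """Independent enumeration oracle for the Kruskal-Wallis test."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    sizes = [len(g) for g in groups]
    _, counts = np.unique(ranks, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)

    def h_of(assign):
        h, start = 0.0, 0
        for size in sizes:
            rs = sum(ranks[i] for i in assign[start:start + size])
            h += rs * rs / size
            start += size
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie

    h_obs = h_of(list(range(n)))
    hits = total = 0
    idx = set(range(n))

    def recurse(remaining, chosen):
        nonlocal hits, total
        if len(chosen) == len(sizes) - 1:
            assign = [i for grp in chosen for i in grp] + sorted(remaining)
            total += 1
            hits += h_of(assign) >= h_obs - 1e-12
            return
        size = sizes[len(chosen)]
        for combo in combinations(sorted(remaining), size):
            recurse(remaining - set(combo), chosen + [list(combo)])

    recurse(idx, [])
    return h_obs, hits / total


class TestKruskalWallisScreen:
    def test_identical_groups_give_p_one(self):
        table = pd.DataFrame({"f": [5.0] * 6}, index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=table.index)
        out = kruskal_wallis_screen(table, groups)
        assert out.loc["f", "pvalue"] == 1.0
        assert out.loc["f", "constant"]

    def test_h_and_p_match_enumeration(self):
        """(1,2,3) vs (4,5,6): H and p against the independent oracle
        (all 20 rank assignments)."""
        table = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]}, index=list("abcdef"))
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=table.index)
        out = kruskal_wallis_screen(table, groups)
        h_ref, p_ref = brute_force_kw([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert out.loc["f", "statistic"] == pytest.approx(h_ref)
        assert out.loc["f", "pvalue"] == pytest.approx(p_ref)
        assert out.loc["f", "pvalue"] == pytest.approx(0.1)

    def test_three_group_exact_matches_enumeration(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=9)
        table = pd.DataFrame({"f": vals})
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=table.index)
        out = kruskal_wallis_screen(table, groups)
        _, p_ref = brute_force_kw([vals[:3], vals[3:6], vals[6:]])
        assert out.loc["f", "pvalue"] == pytest.approx(p_ref)
        assert out.loc["f", "method"] == "exact"

    def test_single_group_rejected(self):
        table = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            kruskal_wallis_screen(table, pd.Series(["x", "x"], index=table.index))


class TestLDAEffectSize:
    @pytest.fixture
    def planted(self):
        def make(fold, n=9, seed=0):
            rng = np.random.default_rng(seed)
            base = np.array([0.30, 0.30, 0.20, 0.10, 0.10])
            rows = []
            for i in range(2 * n):
                comp = base.copy()
                if i >= n:
                    comp[0] *= fold
                comp = comp * rng.lognormal(0, 0.1, 5)
                rows.append(comp / comp.sum())
            table = pd.DataFrame(rows, columns=[f"t{j}" for j in range(5)])
            groups = pd.Series(["LOS"] * n + ["HOS"] * n, index=table.index)
            return table, groups
        return make

    def test_constant_feature_scores_zero(self):
        # equal row totals keep the feature constant on the per-million scale
        table = pd.DataFrame({
            "diff": [1.0, 1.2, 0.9, 5.0, 5.5, 4.8],
            "anti": [5.0, 4.8, 5.1, 1.0, 0.5, 1.2],
            "const": [4.0] * 6,
        })
        table = table.div(table.sum(axis=1), axis=0)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=table.index)
        scores = lda_effect_size(table, groups, seed=1)
        assert scores["const"] == pytest.approx(0.0, abs=1e-6)
        assert scores["diff"] > 2

    def test_monotone_in_planted_fold_change(self, planted):
        scores = []
        for fold in (1, 2, 4, 8, 16):
            table, groups = planted(fold)
            scores.append(lda_effect_size(table, groups, seed=7)["t0"])
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))
        assert scores[-1] > scores[0]

    def test_strong_effect_clears_the_lefse_threshold(self, planted):
        table, groups = planted(100)
        assert lda_effect_size(table, groups, seed=2)["t0"] > 2

    def test_bit_reproducible_under_fixed_seed(self, planted):
        table, groups = planted(4)
        a = lda_effect_size(table, groups, seed=11)
        b = lda_effect_size(table, groups, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_requires_two_groups(self, planted):
        table, groups = planted(2)
        with pytest.raises(ValueError):
            lda_effect_size(table, groups.replace({"HOS": "LOS"}), seed=0)


class TestLefse:
    def test_significance_flag_is_the_conjunction(self, planted_study=None):
        rng = np.random.default_rng(3)
        n = 9
        table = pd.DataFrame(
            rng.lognormal(0, 0.2, (2 * n, 30)), columns=[f"t{j}" for j in range(30)]
        )
        table.iloc[n:, 0] *= 50  # one strong planted taxon
        table = table.div(table.sum(axis=1), axis=0)
        groups = pd.Series(["LOS"] * n + ["HOS"] * n, index=table.index)
        res = lefse(table, groups, seed=5)
        t = res.table
        assert ((t["significant"]) ==
                ((t["pvalue"] < 0.05) & (t["lda_score"] > 2))).all()
        assert t.loc["t0", "significant"]
        assert t.loc["t0", "higher_in"] == "HOS"


class TestWilcoxonFoldChange:
    def _frame(self, x, y):
        table = pd.DataFrame({"f": np.concatenate([x, y])})
        groups = pd.Series(["HOS"] * len(x) + ["LOS"] * len(y), index=table.index)
        return table, groups

    def test_exact_p_for_textbook_case(self):
        table, groups = self._frame([1.0, 2, 3], [4.0, 5, 6])
        out = wilcoxon_fold_change(table, groups)
        assert out.loc["f", "pvalue"] == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        table, groups = self._frame([1.0, 2, 3], [1.0, 2, 3])
        out = wilcoxon_fold_change(table, groups)
        # with every value tied the feature is not constant but symmetric
        assert out.loc["f", "pvalue"] == pytest.approx(1.0)

    def test_exact_matches_brute_force_enumeration(self):
        """Exact two-sided p against enumeration of all C(n1+n2, n1)
        assignments, across several small designs."""
        rng = np.random.default_rng(6)
        for n1, n2 in [(2, 3), (4, 4), (5, 6), (6, 6)]:
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            table, groups = self._frame(x, y)
            p_impl = wilcoxon_fold_change(table, groups).loc["f", "pvalue"]
            pooled = np.concatenate([x, y])
            ranks = rankdata(pooled)
            r_obs = ranks[:n1].sum()
            n = n1 + n2
            mu = n1 * (n + 1) / 2
            hits = total = 0
            for combo in combinations(range(n), n1):
                r = ranks[list(combo)].sum()
                total += 1
                hits += abs(r - mu) >= abs(r_obs - mu) - 1e-12
            assert p_impl == pytest.approx(hits / total), (n1, n2)

    def test_fold_change_orientation_and_pseudo_count(self):
        table, groups = self._frame([4.0, 4.5, 5.0], [2.0, 2.2, 1.8])
        out = wilcoxon_fold_change(table, groups)
        assert out.loc["f", "fold_change"] == pytest.approx(4.5 / 2.0)
        assert out.loc["f", "higher_in"] == "HOS"
        table0, groups0 = self._frame([1.0, 2.0, 1.5], [0.0, 0.0, 0.0])
        out0 = wilcoxon_fold_change(table0, groups0)
        assert out0.loc["f", "pseudo_count"]
        assert np.isfinite(out0.loc["f", "fold_change"])

    def test_planted_moderate_fold_change_detected_at_nine_per_group(self):
        """A 1.44-fold metabolite shift with low noise at n = 9 + 9 is
        detectable at p < 0.05."""
        rng = np.random.default_rng(8)
        base = 1e5
        hos = base * 1.44 * rng.lognormal(0, 0.08, 9)
        los = base * rng.lognormal(0, 0.08, 9)
        table, groups = self._frame(hos, los)
        out = wilcoxon_fold_change(table, groups)
        assert out.loc["f", "pvalue"] < 0.05
        assert out.loc["f", "fold_change"] == pytest.approx(1.44, rel=0.15)

    def test_wrong_group_labels_are_an_error(self):
        table, groups = self._frame([1.0, 2], [3.0, 4])
        with pytest.raises(ValueError):
            wilcoxon_fold_change(table, groups.replace({"HOS": "HI"}))


def test_order_invariance_of_tests():
    """Shuffling sample order leaves every p-value unchanged."""
    rng = np.random.default_rng(9)
    table = pd.DataFrame(rng.lognormal(0, 0.5, (12, 6)),
                         index=[f"s{i}" for i in range(12)])
    groups = pd.Series(["HOS"] * 6 + ["LOS"] * 6, index=table.index)
    perm = table.sample(frac=1, random_state=1).index
    a = kruskal_wallis_screen(table, groups)
    b = kruskal_wallis_screen(table.loc[perm], groups.loc[perm])
    pd.testing.assert_frame_equal(a, b)
    wa = wilcoxon_fold_change(table, groups)["pvalue"]
    wb = wilcoxon_fold_change(table.loc[perm], groups.loc[perm])["pvalue"]
    pd.testing.assert_series_equal(wa, wb)
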