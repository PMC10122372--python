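"""QC filtering, PQN, origin partitioning, and pathway enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from gutosi.metabolome import (MetaboliteTable, OriginAnnotation, classify_origins,
                               pathway_enrichment, pqn_normalize, qc_filter)


def make_table(bio: dict, qc: dict) -> MetaboliteTable:
    rows = {**bio, **qc}
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return MetaboliteTable(intensities=df, qc_samples=list(qc))


class TestQCFilter:
    def test_presence_and_rsd_rules(self):
        table = make_table(
            bio={"s1": {"a": 100, "b": 100, "c": 100, "d": 100}},
            qc={
                "QC1": {"a": 100, "b": np.nan, "c": 100, "d": 100},
                "QC2": {"a": 100, "b": np.nan, "c": 150, "d": 100},
                "QC3": {"a": 100, "b": 50.0, "c": 200, "d": 100},
            },
        )
        res = qc_filter(table)
        # 'b' missing in 2/3 QC -> removed; 'a' RSD 0 -> kept;
        # 'c' = (100,150,200): population RSD = 27.2% -> kept at the 30% bound
        assert res.removed_presence == ["b"]
        assert res.removed_rsd == []
        assert set(res.table.intensities.columns) == {"a", "c", "d"}

    def test_rsd_strictly_above_30_removed(self):
        mu = 100.0
        # three QC values with population RSD exactly 0.30 -> retained (strict >)
        x = mu * (1 - 0.3 * np.sqrt(1.5))
        exact = {"QC1": x, "QC2": mu, "QC3": 2 * mu - x}
        above = {"QC1": 50.0, "QC2": 100.0, "QC3": 200.0}  # RSD 53%
        table = make_table(
            bio={"s1": {"at": 1.0, "over": 1.0}},
            qc={q: {"at": exact[q], "over": above[q]} for q in exact},
        )
        res = qc_filter(table)
        vals = np.array(list(exact.values()))
        assert vals.std(ddof=0) / vals.mean() == pytest.approx(0.30)
        assert "at" in res.table.intensities.columns
        assert res.removed_rsd == ["over"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        bio = {f"s{i}": dict(zip("abcdef", rng.lognormal(10, 1, 6))) for i in range(4)}
        qc = {f"QC{i}": dict(zip("abcdef", rng.lognormal(10, 0.2, 6))) for i in range(4)}
        table = make_table(bio, qc)
        once = qc_filter(table)
        twice = qc_filter(once.table)
        pd.testing.assert_frame_equal(once.table.intensities, twice.table.intensities)
        assert twice.removed_presence == [] and twice.removed_rsd == []

    def test_requires_three_qc_samples(self):
        table = make_table(bio={"s1": {"a": 1.0}},
                           qc={"QC1": {"a": 1.0}, "QC2": {"a": 1.0}})
        with pytest.raises(ValueError, match="QC"):
            qc_filter(table)


class TestPQN:
    def test_exact_multiples_recovered(self):
        ref = {"a": 100.0, "b": 200.0, "c": 400.0}
        table = make_table(
            bio={"s2x": {k: 2 * v for k, v in ref.items()},
                 "shalf": {k: 0.5 * v for k, v in ref.items()}},
            qc={f"QC{i}": dict(ref) for i in (1, 2, 3)},
        )
        res = pqn_normalize(table, log_transform=False)
        assert res.quotients["s2x"] == pytest.approx(2.0)
        assert res.quotients["shalf"] == pytest.approx(0.5)
        for s in ("s2x", "shalf"):
            assert np.allclose(res.table.intensities.loc[s],
                               pd.Series(ref), atol=1e-9)

    def test_quotient_is_median_of_ratios(self):
        rng = np.random.default_rng(1)
        n_feat = 20
        ref = rng.lognormal(10, 1, n_feat)
        bio = {f"s{i}": dict(zip(range(n_feat), rng.lognormal(10, 1, n_feat)))
               for i in range(5)}
        qc = {f"QC{i}": dict(zip(range(n_feat), ref)) for i in (1, 2, 3)}
        table = make_table(bio, qc)
        res = pqn_normalize(table, log_transform=False)
        for s, row in bio.items():
            expected = np.median(np.array(list(row.values())) / ref)
            assert res.quotients[s] == pytest.approx(expected)

    def test_identical_samples_give_unit_quotients(self):
        ref = {"a": 10.0, "b": 20.0}
        table = make_table(
            bio={f"s{i}": dict(ref) for i in range(3)},
            qc={f"QC{i}": dict(ref) for i in (1, 2, 3)},
        )
        res = pqn_normalize(table, log_transform=False)
        assert np.allclose(res.quotients, 1.0)

    def test_per_sample_scaling_invariance(self):
        """Scaling any sample before PQN does not change its normalized row."""
        rng = np.random.default_rng(2)
        ref = dict(zip("abcde", rng.lognormal(8, 1, 5)))
        bio = {f"s{i}": dict(zip("abcde", rng.lognormal(8, 1, 5))) for i in range(3)}
        qc = {f"QC{i}": dict(ref) for i in (1, 2, 3)}
        base = pqn_normalize(make_table(bio, qc), log_transform=False)
        scaled_bio = {s: {k: 7.3 * v for k, v in row.items()} if s == "s1" else row
                      for s, row in bio.items()}
        scaled = pqn_normalize(make_table(scaled_bio, qc), log_transform=False)
        pd.testing.assert_frame_equal(base.table.intensities,
                                      scaled.table.intensities)

    def test_log_state_and_offset(self):
        ref = {"a": 10.0, "b": 20.0}
        table = make_table(bio={"s1": dict(ref)},
                           qc={f"QC{i}": dict(ref) for i in (1, 2, 3)})
        res = pqn_normalize(table)
        assert res.table.state == "pqn+log"
        assert res.log_offset == pytest.approx(5.0)  # half the min positive
        with pytest.raises(ValueError, match="raw"):
            pqn_normalize(res.table)


class TestOrigins:
    def test_empty_annotation_puts_everything_in_others(self):
        ann = OriginAnnotation(origins=pd.Series(dtype=object), pathways={})
        counts, lists = classify_origins(["m1", "m2"], ann)
        assert counts["others"] == 2 and counts.sum() == 2

    def test_toy_partition(self):
        origins = pd.Series({
            **{f"h{i}": "host" for i in range(3)},
            **{f"b{i}": "microbiota" for i in range(2)},
            **{f"c{i}": "cometabolism" for i in range(4)},
            "f0": "food",
        })
        ann = OriginAnnotation(origins=origins, pathways={})
        counts, _ = classify_origins(origins.index, ann)
        assert counts.to_dict() == {"host": 3, "microbiota": 2,
                                    "cometabolism": 4, "others": 1}

    def test_duplicate_annotation_is_an_error(self):
        dup = pd.Series(["host", "food"], index=["m1", "m1"])
        with pytest.raises(ValueError, match="duplicate"):
            OriginAnnotation(origins=dup, pathways={})

    def test_counts_conserve_input_size(self):
        rng = np.random.default_rng(3)
        feats = [f"m{i}" for i in range(50)]
        origins = pd.Series(rng.choice(["host", "microbiota", "unknown"], 30),
                            index=feats[:30])
        ann = OriginAnnotation(origins=origins, pathways={})
        counts, _ = classify_origins(feats, ann)
        assert counts.sum() == 50


def hypergeom_tail(N, K, n, k):
    """P(X >= k) by direct combinatorial summation."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) \
        / comb(N, n)


class TestEnrichment:
    def _annotation(self, n_cat=20, in_pathway=5):
        feats = [f"m{i:02d}" for i in range(n_cat)]
        origins = pd.Series("microbiota", index=feats)
        pathways = {f: ({"pwX"} if i < in_pathway else set())
                    for i, f in enumerate(feats)}
        return feats, OriginAnnotation(origins=origins, pathways=pathways)

    def test_zero_overlap_gives_p_one(self):
        feats, ann = self._annotation()
        res = pathway_enrichment(feats[10:12], feats, ann)  # outside pwX
        assert (res.loc[res["pathway"] == "pwX", "pvalue"] == 1.0).all()

    def test_matches_exact_combinatorial_sum(self):
        feats, ann = self._annotation(n_cat=20, in_pathway=5)
        diff = feats[:3] + feats[10:13]  # k=3 of the 5 members, n=6
        res = pathway_enrichment(diff, feats, ann)
        row = res[res["pathway"] == "pwX"].iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (20, 5, 6, 3)
        assert row["pvalue"] == pytest.approx(hypergeom_tail(20, 5, 6, 3))

    def test_saturated_case_gives_p_one(self):
        feats, ann = self._annotation()
        res = pathway_enrichment(feats, feats, ann)
        assert np.allclose(res["pvalue"], 1.0)

    def test_differential_outside_universe_is_an_error(self):
        feats, ann = self._annotation()
        with pytest.raises(ValueError, match="subset"):
            pathway_enrichment(["mZZ"], feats, ann)

    def test_enrichment_runs_per_origin_category(self):
        feats = [f"m{i}" for i in range(10)]
        origins = pd.Series(["host"] * 5 + ["microbiota"] * 5, index=feats)
        pathways = {f: {"pw1"} for f in feats}
        ann = OriginAnnotation(origins=origins, pathways=pathways)
        res = pathway_enrichment(feats[:2], feats, ann)
        assert set(res["origin"]) == {"host", "microbiota"}
        host = res[res["origin"] == "host"].iloc[0]
        assert host["N"] == 5 and host["n"] == 2
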