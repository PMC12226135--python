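"""Preranked GSEA against a brute-force oracle, ORA against exact enumeration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirscore import (
    benchmark_validated,
    extract_top_targets,
    ora_enrich,
    preranked_gsea,
    user_list_mirna_enrichment,
)
from mirscore.bundle import ValidatedTargetCatalog
from mirscore.enrichment import enrichment_score, read_gmt, write_gmt


def brute_force_es(genes, scores, gene_set, weight=1.0):
    """Literal running-sum ES: evaluate every prefix, pick the larger excursion."""
    n = len(genes)
    hits = [g in gene_set for g in genes]
    k = sum(hits)
    total = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, values = 0.0, [0.0]
    for g, s, h in zip(genes, scores, hits):
        run += (abs(s) ** weight) / total if h else -1.0 / (n - k)
        values.append(run)
    mx, mn = max(values), min(values)
    return mx if mx >= -mn - 1e-12 else mn


class TestEnrichmentScore:
    def test_top_block_scores_one(self):
        genes = [f"g{i}" for i in range(10)]
        scores = np.arange(10, 0, -1, dtype=float)
        assert enrichment_score(genes, scores, {"g0", "g1", "g2"}) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        """ES equals a literal prefix-sum oracle to 1e-12 on random rankings."""
        rng = np.random.default_rng(0)
        genes = np.array([f"g{i}" for i in range(10)])
        for _ in range(300):
            scores = rng.normal(0, 1, 10)
            order = np.argsort(-scores)
            g, s = genes[order], scores[order]
            size = int(rng.integers(1, 9))
            gene_set = set(rng.choice(genes, size, replace=False))
            assert enrichment_score(g, s, gene_set) == pytest.approx(
                brute_force_es(list(g), list(s), gene_set), abs=1e-12
            )

    def test_reversing_ranking_negates_es(self):
        genes = [f"g{i}" for i in range(20)]
        scores = np.linspace(10, -10, 20)
        gene_set = {"g0", "g3", "g5"}
        es_fwd = enrichment_score(genes, scores, gene_set)
        es_rev = enrichment_score(genes[::-1], scores[::-1], gene_set)
        assert es_fwd > 0
        # with weight 1 the hit weights differ after reversal, so assert sign
        assert es_rev < 0

    def test_whole_ranking_set_degenerates_to_zero(self):
        genes = ["a", "b", "c"]
        with pytest.warns(UserWarning, match="entire ranking"):
            es = enrichment_score(genes, np.array([3.0, 2.0, 1.0]), set(genes))
        assert es == 0.0


class TestPrerankedGsea:
    def _ranking(self, n=50):
        return pd.Series(np.linspace(100, 1, n), index=[f"g{i}" for i in range(n)])

    def test_p_floor_and_reproducibility(self):
        ranked = self._ranking()
        res1 = preranked_gsea(ranked, {"g0", "g1", "g2"}, n_perm=200, seed=3)
        res2 = preranked_gsea(ranked, {"g0", "g1", "g2"}, n_perm=200, seed=3)
        assert res1.p >= 1.0 / 201
        assert res1.p == res2.p and res1.nes == res2.nes

    def test_empty_overlap_warns_with_p_one(self):
        with pytest.warns(UserWarning, match="overlap"):
            res = preranked_gsea(self._ranking(), {"absent"}, n_perm=100, seed=0)
        assert res.p == 1.0 and res.es is None

    def test_top_set_significant_bottom_set_not_positive(self):
        ranked = self._ranking(100)
        top = preranked_gsea(ranked, {f"g{i}" for i in range(8)}, n_perm=500, seed=4)
        bottom = preranked_gsea(ranked, {f"g{i}" for i in range(92, 100)}, n_perm=500, seed=4)
        assert top.es > 0 and top.p < 0.05
        assert bottom.es < 0

    def test_null_p_values_roughly_uniform(self):
        """Random 20-gene sets on a random 300-gene ranking: p ~ U(0,1)."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(300)]
        scores = np.sort(rng.normal(0, 1, 300))[::-1]
        ranked = pd.Series(scores, index=genes)
        ps = []
        for i in range(200):
            gene_set = set(rng.choice(genes, 20, replace=False))
            ps.append(preranked_gsea(ranked, gene_set, n_perm=200, seed=i).p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.005


class TestBenchmark:
    def test_planted_catalog_fully_enriched(self, small_system):
        """Validated sets drawn from planted targets: every miRNA enriched."""
        bench = benchmark_validated(
            small_system["table"], small_system["catalog"],
            min_targets=10, n_perm=200, seed=1,
        )
        assert len(bench) == 6
        assert bench["significant"].all()
        assert (bench["es"] > 0).all()

    def test_min_target_rule_excludes_small_catalogs(self, small_system):
        catalog = small_system["catalog"]
        mirna = catalog.records["mirna"].iloc[0]
        trimmed = catalog.records[
            ~((catalog.records["mirna"] == mirna)
              & (catalog.records.groupby("mirna").cumcount() >= 9))
        ]
        small_cat = ValidatedTargetCatalog(records=trimmed)
        assert len(small_cat.targets_of(mirna, "luciferase_reporter")) == 9
        bench = benchmark_validated(
            small_system["table"], small_cat, min_targets=10, n_perm=200, seed=1
        )
        assert mirna not in set(bench["mirna"])

    def test_scrambled_catalog_enrichment_near_alpha(self, small_system):
        """Randomly re-paired validated targets: enrichment fraction collapses."""
        rng = np.random.default_rng(7)
        records = small_system["catalog"].records.copy()
        genes = small_system["table"].genes
        records["gene"] = rng.choice(genes, len(records), replace=False)
        records = records.drop_duplicates(subset=["mirna", "gene", "pmid"])
        bench = benchmark_validated(
            small_system["table"], ValidatedTargetCatalog(records=records),
            min_targets=10, n_perm=200, seed=2,
        )
        assert bench["significant"].mean() <= 0.35


class TestOra:
    def test_exact_hypergeometric(self):
        """Overlap 4 of a 5-gene set, 5-gene query, 20-gene universe."""
        universe = {f"g{i}" for i in range(20)}
        res = ora_enrich(
            ["g0", "g1", "g2", "g3", "g10"],
            {"s": {"g0", "g1", "g2", "g3", "g4"}},
            universe,
        )
        # exact enumeration: (C(5,4)*C(15,1) + C(5,5)*C(15,0)) / C(20,5)
        expected = (5 * 15 + 1) / 15504
        assert res["p"][0] == pytest.approx(expected, abs=1e-12)
        assert res["overlap_genes"][0] == "G0,G1,G2,G3"

    def test_matches_enumeration_for_small_universes(self):
        """P[X >= k] agrees with explicit enumeration over all draws, N <= 25."""
        from math import comb

        rng = np.random.default_rng(8)
        for _ in range(50):
            n_u = int(rng.integers(5, 26))
            universe = [f"g{i}" for i in range(n_u)]
            set_size = int(rng.integers(1, n_u))
            query_size = int(rng.integers(1, n_u))
            members = set(rng.choice(universe, set_size, replace=False))
            query = list(rng.choice(universe, query_size, replace=False))
            k_obs = len(members & set(query))
            p_enum = sum(
                comb(set_size, k) * comb(n_u - set_size, query_size - k)
                for k in range(k_obs, min(set_size, query_size) + 1)
            ) / comb(n_u, query_size)
            res = ora_enrich(query, {"s": members}, set(universe))
            assert res["p"][0] == pytest.approx(p_enum, abs=1e-12)

    def test_disjoint_query_p_one(self):
        res = ora_enrich(["g0"], {"s": {"g5", "g6"}}, {f"g{i}" for i in range(10)})
        assert res["p"][0] == 1.0

    def test_query_equals_set_equals_universe(self):
        genes = {"g0", "g1", "g2"}
        res = ora_enrich(list(genes), {"s": genes}, genes)
        assert res["p"][0] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ora_enrich([], {"s": {"g0"}}, {"g0"})

    def test_bh_matches_literal_step_up(self):
        """FDR equals a from-scratch Benjamini-Hochberg step-up transform."""
        rng = np.random.default_rng(9)
        universe = {f"g{i}" for i in range(100)}
        sets = {
            f"s{j}": set(rng.choice(sorted(universe), 10, replace=False))
            for j in range(20)
        }
        res = ora_enrich(list(rng.choice(sorted(universe), 15, replace=False)),
                         sets, universe)
        p = res["p"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        stepped = np.empty(m)
        running_min = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running_min = min(running_min, p[idx] * m / (rank_pos + 1))
            stepped[idx] = running_min
        assert np.allclose(res["fdr"].to_numpy(), stepped, atol=1e-12)


class TestUserListEnrichment:
    def test_self_consistency_top_hit(self, small_system):
        """A user list built from one miRNA's top targets names that miRNA first."""
        table = small_system["table"]
        mirna = table.mirnas[0]
        user = extract_top_targets(table, mirna, 25)
        res = user_list_mirna_enrichment(user, table, k=25)
        assert res.iloc[0]["set_name"] == mirna
        assert res.iloc[0]["fdr"] < 0.05

    def test_co_targeting_family_all_rank_high(self):
        """miRNAs sharing most of their targets all surface for a shared list."""
        from mirscore.scoring import ScoreTable, rank_bidirectional

        rng = np.random.default_rng(10)
        genes = [f"G{i:03d}" for i in range(400)]
        shared = genes[:30]
        rows = []
        for fam in ("mir-f1", "mir-f2", "mir-f3", "mir-f4"):
            own = list(rng.choice(genes[30:], 20, replace=False))
            targets = shared + own  # 60 % of the top-50 set is shared
            scores = {g: 100 - i for i, g in enumerate(targets)}
            for g in genes:
                rows.append((fam, g, scores.get(g, rng.uniform(0, 5))))
        for outsider in ("mir-o1", "mir-o2", "mir-o3"):
            for g in genes:
                rows.append((outsider, g, rng.uniform(0, 100)))
        frame = pd.DataFrame(rows, columns=["mirna", "gene", "composite"])
        table = ScoreTable(rank_bidirectional(frame))
        res = user_list_mirna_enrichment(shared, table, k=50)
        top5 = set(res.head(5)["set_name"])
        assert {"mir-f1", "mir-f2", "mir-f3", "mir-f4"} <= top5

    def test_null_user_lists_do_not_flag(self, small_system):
        """Uniformly drawn user lists: min FDR rarely below alpha."""
        rng = np.random.default_rng(11)
        table = small_system["table"]
        genes = table.genes
        hits = 0
        n_seeds = 60
        for _ in range(n_seeds):
            user = list(rng.choice(genes, 30, replace=False))
            res = user_list_mirna_enrichment(user, table, k=50)
            if res["fdr"].min() < 0.05:
                hits += 1
        assert hits / n_seeds <= 0.15


def test_gmt_roundtrip(tmp_path):
    sets = {"SET_A": {"TP53", "CDC7"}, "SET_B": {"DBF4", "MET", "AXL"}}
    path = tmp_path / "c.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
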