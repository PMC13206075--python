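"""Enrichment-score walk, leading edge, permutation inference and ORA,
checked against brute-force oracles and an independent implementation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dedtarget import (GeneSetCollection, RankedGeneList, ValidationError,
                       enrichment_score, leading_edge, ora_hypergeometric,
                       preranked_gsea)
from conftest import running_sum_walk


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(0, 1, n))[::-1]
    return RankedGeneList([f"g{i:02d}" for i in range(n)], scores)


class TestEnrichmentScore:
    def test_single_top_gene_gives_es_one(self):
        ranked = _ranked(10)
        es, peak = enrichment_score(ranked, {ranked.genes[0]})
        assert es == pytest.approx(1.0)
        assert peak == 0

    def test_antisymmetry_under_negated_reversed_list(self):
        ranked = _ranked(12, seed=3)
        members = {ranked.genes[2], ranked.genes[7], ranked.genes[9]}
        es, _ = enrichment_score(ranked, members)
        flipped = RankedGeneList(ranked.genes[::-1], -ranked.scores[::-1])
        es_f, _ = enrichment_score(flipped, members)
        assert es_f == pytest.approx(-es)

    def test_six_gene_walk_matches_step_oracle(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        scores = np.array([3.0, 2.0, 1.0, -0.5, -1.5, -2.5])
        ranked = RankedGeneList(genes, scores)
        members = {"b", "e"}
        es, peak = enrichment_score(ranked, members)
        es_o, peak_o = running_sum_walk(genes, scores, members)
        assert es == pytest.approx(es_o)
        assert peak == peak_o

    def test_exhaustive_small_lists_match_oracle(self):
        """Every list length up to 8 x every member subset of size <= 3."""
        for n in range(3, 9):
            ranked = _ranked(n, seed=n)
            for k in (1, 2, 3):
                for combo in itertools.combinations(ranked.genes, k):
                    if k >= n:
                        continue
                    es, peak = enrichment_score(ranked, set(combo))
                    es_o, peak_o = running_sum_walk(
                        ranked.genes, ranked.scores, set(combo))
                    assert es == pytest.approx(es_o), (n, combo)
                    assert peak == peak_o, (n, combo)
                    assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
                    le = leading_edge(ranked, set(combo), es, peak)
                    pos = ranked.position()
                    if es > 0:
                        assert set(le) == {g for g in combo
                                           if pos[g] <= peak}
                    elif es < 0:
                        assert set(le) == {g for g in combo
                                           if pos[g] >= peak}

    def test_weight_zero_invariant_to_monotone_rescaling(self):
        ranked = _ranked(15, seed=6)
        members = set(ranked.genes[i] for i in (1, 5, 11))
        es1, _ = enrichment_score(ranked, members, weight=0)
        rescaled = RankedGeneList(ranked.genes, ranked.scores * 7.5 )
        es2, _ = enrichment_score(rescaled, members, weight=0)
        assert es1 == pytest.approx(es2)

    def test_empty_and_covering_sets_rejected(self):
        ranked = _ranked(5)
        with pytest.raises(ValidationError):
            enrichment_score(ranked, set())
        with pytest.raises(ValidationError):
            enrichment_score(ranked, set(ranked.genes))

    def test_matches_independent_gsea_implementation(self):
        """Cross-check the weighted ES against gseapy on a random fixture."""
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        ranked = _ranked(60, seed=8)
        rng = np.random.default_rng(4)
        sets = {f"S{i}": list(rng.choice(ranked.genes, 10, replace=False))
                for i in range(3)}
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": ranked.genes, "score": ranked.scores}),
            gene_sets=sets, permutation_num=10, min_size=2, max_size=500,
            weight=1, seed=1, outdir=None, no_plot=True).res2d
        for name, members in sets.items():
            ours, _ = enrichment_score(ranked, members, weight=1)
            theirs = float(res.loc[res.Term == name, "ES"].iloc[0])
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestLeadingEdge:
    def test_single_member_at_top(self):
        ranked = _ranked(10)
        es, peak = enrichment_score(ranked, {ranked.genes[0]})
        assert leading_edge(ranked, {ranked.genes[0]}, es, peak) == \
            [ranked.genes[0]]

    def test_all_members_before_peak_all_in_edge(self):
        genes = ["a", "b", "c", "d", "e", "f"]
        scores = np.array([5.0, 4.0, 3.0, 0.1, 0.05, 0.01])
        ranked = RankedGeneList(genes, scores)
        es, peak = enrichment_score(ranked, {"a", "b", "c"})
        assert leading_edge(ranked, {"a", "b", "c"}, es, peak) == \
            ["a", "b", "c"]

    def test_zero_es_gives_empty_subset(self):
        ranked = _ranked(6)
        assert leading_edge(ranked, {"g01"}, 0.0, 2) == []


class TestPrerankedGsea:
    def test_planted_set_recovered_across_seeds(self, small_config):
        """The planted active sets come out significant with the planted
        direction in nearly all seeded replicates."""
        from dedtarget import (differential_expression, filter_low_counts,
                               generate_counts, generate_gene_sets,
                               rank_genes)
        hits = trials = 0
        for rep in range(10):
            cfg = type(small_config)(
                n_datasets=1, n_genes=400, n_gene_sets=12, n_active_sets=4,
                consensus_support=1, seed=700 + rep)
            datasets, truth = generate_counts(cfg)
            coll = generate_gene_sets(cfg)
            de = differential_expression(filter_low_counts(datasets[0]))
            results = {r.name: r for r in preranked_gsea(
                rank_genes(de), coll, n_perm=200, seed=rep)}
            for name, info in truth.active_sets.items():
                if "D1" not in info["datasets"]:
                    continue
                trials += 1
                r = results[name]
                hits += (r.pvalue < 0.05 and r.direction == info["direction"])
        assert hits / trials >= 0.95

    def test_null_calibration(self):
        """Random scores: about 5% of sets reach p < 0.05."""
        rng = np.random.default_rng(0)
        flags = []
        for rep in range(5):
            scores = np.sort(rng.normal(0, 1, 300))[::-1]
            ranked = RankedGeneList([f"g{i}" for i in range(300)], scores)
            sets = {f"S{i}": [f"g{j}" for j in
                              rng.choice(300, 15, replace=False)]
                    for i in range(40)}
            res = preranked_gsea(ranked, GeneSetCollection(sets),
                                 n_perm=200, seed=rep)
            flags += [r.pvalue < 0.05 for r in res]
        se = np.sqrt(0.05 * 0.95 / len(flags))
        assert np.mean(flags) <= 0.05 + 3 * se

    def test_pvalues_in_unit_interval_and_never_zero(self, small_config):
        from dedtarget import (differential_expression, filter_low_counts,
                               generate_counts, generate_gene_sets,
                               rank_genes)
        datasets, _ = generate_counts(small_config)
        coll = generate_gene_sets(small_config)
        de = differential_expression(filter_low_counts(datasets[0]))
        res = preranked_gsea(rank_genes(de), coll, n_perm=200, seed=1)
        for r in res:
            assert 0 < r.pvalue <= 1
            if r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)
                assert r.direction == ("up" if r.es > 0 else "down")
                assert set(r.leading_edge) <= set(coll[r.name])

    def test_determinism_and_mc_convergence(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(0, 1, 200))[::-1]
        ranked = RankedGeneList([f"g{i}" for i in range(200)], scores)
        sets = GeneSetCollection(
            {"S": [f"g{i}" for i in range(0, 40, 2)]})
        p1 = preranked_gsea(ranked, sets, n_perm=400, seed=7)[0].pvalue
        p1b = preranked_gsea(ranked, sets, n_perm=400, seed=7)[0].pvalue
        p2 = preranked_gsea(ranked, sets, n_perm=800, seed=9)[0].pvalue
        assert p1 == p1b
        # binomial MC error bound at ~3 sigma
        se = np.sqrt(p1 * (1 - p1) / 400) + np.sqrt(p2 * (1 - p2) / 800)
        assert abs(p1 - p2) <= 3 * max(se, 0.01)


class TestOra:
    def test_disjoint_query_gives_p_one(self):
        coll = GeneSetCollection({"S": ["a", "b"]})
        universe = {"a", "b", "c", "d", "e"}
        table = ora_hypergeometric({"c", "d"}, coll, universe)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_full_overlap_is_minimal_p(self):
        universe = {f"g{i}" for i in range(30)}
        coll = GeneSetCollection({"S": ["g0", "g1", "g2"]})
        table = ora_hypergeometric({"g0", "g1", "g2"}, coll, universe)
        expected = stats.hypergeom.pmf(3, 30, 3, 3)
        assert table.loc[0, "p"] == pytest.approx(expected)

    def test_matches_direct_summation(self):
        """N=100, K=10, n=10, k=5: tail by explicit summation."""
        universe = [f"g{i}" for i in range(100)]
        members = universe[:10]
        query = members[:5] + universe[50:55]
        coll = GeneSetCollection({"S": members})
        table = ora_hypergeometric(set(query), coll, set(universe))
        from math import comb
        direct = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) \
            / comb(100, 10)
        assert table.loc[0, "p"] == pytest.approx(direct)

    def test_empty_query_rejected(self):
        coll = GeneSetCollection({"S": ["a"]})
        with pytest.raises(ValidationError):
            ora_hypergeometric(set(), coll, {"a", "b"})
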