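"""Differential-expression stage: filtering rule, median-of-ratios
normalization, moderated fold changes, DEG calling and ranking."""

import numpy as np
import pandas as pd
import pytest

from dedtarget import (CountMatrix, ValidationError, call_degs,
                       differential_expression, estimate_size_factors,
                       filter_low_counts, rank_genes)


def _cm(rows, genes, samples=("c1", "c2", "t1", "t2")):
    groups = {s: ("control" if s.startswith("c") else "treatment")
              for s in samples}
    return CountMatrix(pd.DataFrame(rows, index=genes, columns=samples), groups)


class TestFilterLowCounts:
    def test_union_keeps_gene_expressed_in_one_group_only(self):
        # control total 0, treatment total 12: "either group" keeps it
        cm = _cm([[0, 0, 5, 7], [20, 20, 20, 20]], ["lowc", "high"])
        kept = filter_low_counts(cm, min_count=10)
        assert kept.genes == ["lowc", "high"]

    def test_intersection_mode_requires_both_groups(self):
        cm = _cm([[0, 0, 5, 7], [20, 20, 20, 20]], ["lowc", "high"])
        kept = filter_low_counts(cm, min_count=10, mode="intersection")
        assert kept.genes == ["high"]

    def test_all_zero_gene_removed(self):
        cm = _cm([[0, 0, 0, 0], [20, 20, 20, 20]], ["zero", "high"])
        assert filter_low_counts(cm).genes == ["high"]

    def test_five_gene_matrix_matches_rule_enumeration(self):
        rows = [[9, 0, 0, 0],      # totals (9, 0): drop
                [5, 5, 0, 0],      # (10, 0): keep via control
                [0, 0, 4, 6],      # (0, 10): keep via treatment
                [4, 5, 4, 5],      # (9, 9): drop
                [6, 6, 6, 6]]      # (12, 12): keep
        genes = ["g1", "g2", "g3", "g4", "g5"]
        cm = _cm(rows, genes)
        expected = [g for g, r in zip(genes, rows)
                    if r[0] + r[1] >= 10 or r[2] + r[3] >= 10]
        assert filter_low_counts(cm, 10).genes == expected == ["g2", "g3", "g5"]

    def test_empty_result_is_explicit_error(self):
        cm = _cm([[1, 1, 1, 1], [2, 0, 1, 0]], ["a", "b"])
        with pytest.raises(ValidationError, match="no genes pass filter"):
            filter_low_counts(cm, min_count=1000)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm([[10, 10, 10, 10], [55, 55, 55, 55]], ["a", "b"])
        assert np.allclose(estimate_size_factors(cm), 1.0)

    def test_doubled_column_scales_factor(self):
        counts = pd.DataFrame({"c1": [10, 100], "c2": [20, 200],
                               "t1": [10, 100], "t2": [20, 200]},
                              index=["a", "b"])
        cm = CountMatrix(counts, {"c1": "control", "c2": "control",
                                  "t1": "treatment", "t2": "treatment"})
        sf = estimate_size_factors(cm)
        assert sf["c2"] / sf["c1"] == pytest.approx(2.0)

    def test_matches_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame(
            [[4, 8, 16], [10, 10, 10], [0, 6, 12], [9, 18, 36]],
            index=["a", "b", "c", "d"], columns=["s1", "s2", "s3"])
        # independent oracle: gene c has a zero, so reference genes are
        # a, b, d with geometric means (8, 10, 18); per-sample ratio
        # medians computed by hand below
        ref = {g: np.exp(np.mean(np.log(counts.loc[g])))
               for g in ["a", "b", "d"]}
        expected = {
            s: np.median([counts.loc[g, s] / ref[g] for g in ["a", "b", "d"]])
            for s in counts.columns
        }
        cm = CountMatrix(
            pd.concat([counts, counts], axis=1, keys=None).set_axis(
                ["s1", "s2", "s3", "s4", "s5", "s6"], axis=1),
            {"s1": "control", "s2": "control", "s3": "control",
             "s4": "treatment", "s5": "treatment", "s6": "treatment"})
        sf = estimate_size_factors(cm)
        for s in ["s1", "s2", "s3"]:
            assert sf[s] == pytest.approx(expected[s])

    def test_error_when_no_gene_covers_all_samples(self):
        cm = _cm([[0, 1, 1, 1], [1, 0, 1, 1]], ["a", "b"])
        with pytest.raises(ValidationError, match="pseudo-reference"):
            estimate_size_factors(cm)


class TestDifferentialExpression:
    def test_identical_groups_give_zero_log2fc(self):
        cm = _cm([[10, 14, 10, 14], [100, 120, 100, 120]], ["a", "b"])
        de = differential_expression(cm)
        assert np.allclose(de["log2FoldChange"], 0.0)
        assert (de["padj"] >= de["pvalue"] - 1e-12).all()

    def test_padj_monotone_in_pvalue_rank(self, small_config):
        from dedtarget import generate_counts
        datasets, _ = generate_counts(small_config)
        de = differential_expression(filter_low_counts(datasets[0]))
        ordered = de.sort_values("pvalue")
        assert (np.diff(ordered["padj"]) >= -1e-12).all()

    def test_bh_invariant_to_input_order(self, small_config):
        from dedtarget import generate_counts
        datasets, _ = generate_counts(small_config)
        cm = filter_low_counts(datasets[0])
        de1 = differential_expression(cm)
        perm = np.random.default_rng(0).permutation(cm.genes)
        de2 = differential_expression(cm.subset_genes(perm))
        pd.testing.assert_series_equal(
            de1["padj"].sort_index(), de2["padj"].sort_index())

    def test_planted_signal_recovered(self):
        from dedtarget import SimulationConfig, generate_counts
        cfg = SimulationConfig(n_datasets=1, n_genes=200, n_gene_sets=6,
                               n_active_sets=2, consensus_support=1,
                               n_samples_per_group=20, seed=8)
        datasets, truth = generate_counts(cfg)
        de = differential_expression(filter_low_counts(datasets[0]))
        planted = {g: v for g, v in truth.de_genes["D1"].items()
                   if g in de.index}
        est = de.loc[list(planted), "log2FoldChange"] * np.sign(
            pd.Series(planted))
        assert abs(est.median() - 2.0) < 0.3


class TestCallDegs:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2FoldChange", "padj"]) \
            .assign(baseMean=1.0, pvalue=lambda f: f["padj"])

    def test_threshold_is_strict(self):
        res = self._results([("exact", 1.0, 0.01), ("above", 1.01, 0.01),
                             ("alpha_exact", 2.0, 0.05)])
        assert call_degs(res) == {"above"}

    def test_large_fc_but_nonsignificant_excluded(self):
        res = self._results([("big", 3.0, 0.2)])
        assert call_degs(res) == set()

    def test_toy_table_matches_enumeration(self):
        rows = [("a", 2.0, 0.01), ("b", -1.5, 0.04), ("c", 0.5, 0.001),
                ("d", 1.2, 0.06), ("e", -3.0, 0.049), ("f", 1.0, 0.01)]
        res = self._results(rows)
        expected = {g for g, lfc, q in rows if abs(lfc) > 1 and q < 0.05}
        assert call_degs(res) == expected == {"a", "b", "e"}


class TestRankGenes:
    def _results(self, pairs):
        return pd.DataFrame({"gene": [g for g, _ in pairs],
                             "log2FoldChange": [v for _, v in pairs],
                             "baseMean": 1.0, "pvalue": 0.5, "padj": 0.5})

    def test_descending_order(self):
        ranked = rank_genes(self._results([("A", 2.0), ("B", -1.0)]))
        assert ranked.genes == ["A", "B"]

    def test_ties_broken_lexicographically(self):
        ranked = rank_genes(self._results([("zz", 1.0), ("aa", 1.0),
                                           ("mm", 1.0)]))
        assert ranked.genes == ["aa", "mm", "zz"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        pairs = [(f"g{i}", float(v)) for i, v in
                 enumerate(rng.normal(size=10))]
        oracle = [g for g, _ in sorted(pairs, key=lambda kv: (-kv[1], kv[0]))]
        assert rank_genes(self._results(pairs)).genes == oracle

    def test_duplicate_gene_raises(self):
        with pytest.raises(ValidationError):
            rank_genes(self._results([("a", 1.0), ("a", 2.0)]))


def test_null_simulation_controls_type_i_error():
    """On no-effect simulations the padj<0.05 discovery rate stays at or
    below nominal plus Monte-Carlo error."""
    from dedtarget import SimulationConfig, generate_counts
    rates = []
    for rep in range(10):
        cfg = SimulationConfig(n_datasets=1, n_genes=300, n_active_sets=0,
                               n_gene_sets=4, consensus_support=1,
                               n_samples_per_group=6, seed=500 + rep)
        datasets, _ = generate_counts(cfg)
        de = differential_expression(filter_low_counts(datasets[0]))
        rates.append((de["padj"] < 0.05).mean())
    n_tests = 10 * 300
    se = np.sqrt(0.05 * 0.95 / n_tests)
    assert np.mean(rates) <= 0.05 + 3 * se
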