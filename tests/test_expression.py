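"""Differential expression, co-expression, median split and GSEA."""

import itertools

import numpy as np
import pytest

from mrscreen import (ExprSimConfig, ExpressionMatrix,
                      differential_expression, gene_correlation,
                      gsea_preranked, simulate_expression,
                      split_by_expression)
from mrscreen.expression import read_expression_tsv, read_gmt, \
    write_expression_tsv


def matrix(values, groups=None, gene_ids=None):
    values = np.asarray(values, float)
    g, s = values.shape
    if groups is None:
        groups = ["case"] * (s // 2) + ["control"] * (s - s // 2)
    gene_ids = gene_ids or [f"G{i+1}" for i in range(g)]
    return ExpressionMatrix(gene_ids, [f"S{k+1}" for k in range(s)],
                            values, groups)


class TestDifferentialExpression:
    def test_equal_means_not_significant(self, rng):
        x = matrix(rng.normal(5, 0.1, (10, 20)))
        recs = differential_expression(x)
        assert all(not r.significant for r in recs)

    def test_clean_spike_recovered(self, rng):
        vals = rng.normal(5, 0.05, (50, 40))
        vals[7, :20] += 2.0  # 4-fold in group A
        recs = differential_expression(matrix(vals))
        sig = [r.gene_id for r in recs if r.significant]
        assert sig == ["G8"]
        assert recs[7].log2fc == pytest.approx(2.0, abs=0.1)

    def test_constant_gene_gets_p_one(self):
        vals = np.vstack([np.full(8, 3.0), np.arange(8, dtype=float)])
        recs = differential_expression(matrix(vals))
        assert recs[0].pvalue == 1.0
        assert not recs[0].significant

    def test_label_swap_negates_fold_changes(self, rng):
        vals = rng.normal(5, 0.5, (30, 16))
        x = matrix(vals)
        fwd = differential_expression(x, group_a="case", group_b="control")
        rev = differential_expression(x, group_a="control", group_b="case")
        np.testing.assert_allclose([r.log2fc for r in fwd],
                                   [-r.log2fc for r in rev])
        np.testing.assert_allclose([r.pvalue for r in fwd],
                                   [r.pvalue for r in rev])

    def test_small_group_fatal(self, rng):
        x = matrix(rng.normal(5, 1, (4, 3)), groups=["case", "case",
                                                     "control"])
        with pytest.raises(ValueError, match=">=2"):
            differential_expression(x)

    def test_fold_change_gate_blocks_small_shifts(self, rng):
        vals = rng.normal(5, 0.01, (20, 40))
        vals[3, :20] += 0.5  # strongly significant but |lfc| < 1
        recs = differential_expression(matrix(vals))
        assert not recs[3].significant
        assert recs[3].adj_pvalue < 0.05


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = matrix(rng.normal(5, 1, (3, 10)))
        res = gene_correlation(x, "G1", ["G1"])[0]
        assert res.r == pytest.approx(1.0)

    def test_negated_gene_gives_minus_one(self, rng):
        base = rng.normal(0, 1, 10)
        x = matrix(np.vstack([5 + base, 5 - base]))
        res = gene_correlation(x, "G1", ["G2"])[0]
        assert res.r == pytest.approx(-1.0)

    def test_textbook_formulas_on_toy_vectors(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        x = matrix(np.vstack([a, b]))
        res = gene_correlation(x, "G1", ["G2"])[0]
        r_hand = float(np.corrcoef(a, b)[0, 1])
        t = r_hand * np.sqrt(8 / (1 - r_hand**2))
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t), df=8)
        assert res.r == pytest.approx(r_hand, rel=1e-12)
        assert res.pvalue == pytest.approx(p_hand, rel=1e-9)

    def test_symmetry(self, rng):
        x = matrix(rng.normal(5, 1, (2, 12)))
        r_ab = gene_correlation(x, "G1", ["G2"])[0].r
        r_ba = gene_correlation(x, "G2", ["G1"])[0].r
        assert r_ab == pytest.approx(r_ba, abs=1e-15)

    def test_zero_variance_reported_missing(self, rng):
        x = matrix(np.vstack([np.full(10, 2.0), rng.normal(0, 1, 10)]))
        res = gene_correlation(x, "G1", ["G2"])[0]
        assert res.r is None
        assert res.reason == "zero variance"


class TestMedianSplit:
    def test_even_split(self):
        x = matrix(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert split_by_expression(x, "G1") == ["low", "low", "high", "high"]

    def test_all_equal_goes_high(self):
        x = matrix(np.full((1, 4), 7.0))
        assert split_by_expression(x, "G1") == ["high"] * 4

    def test_groups_near_balanced_without_ties(self, rng):
        for _ in range(10):
            s = int(rng.integers(4, 30))
            x = matrix(rng.normal(0, 1, (1, s)))
            labels = split_by_expression(x, "G1")
            assert abs(labels.count("high") - labels.count("low")) <= 1


def _es_oracle(positions, scores, weight, k):
    """Independent running-sum ES for a set marked by positions."""
    g = len(scores)
    hits = np.zeros(g)
    hits[list(positions)] = np.abs(scores[list(positions)]) ** weight
    if hits.sum() > 0:
        hits = hits / hits.sum()
    else:
        hits[list(positions)] = 1 / k
    miss = np.ones(g) / (g - k)
    miss[list(positions)] = 0.0
    run = np.cumsum(hits - miss)
    return run[np.argmax(np.abs(run))]


class TestGSEA:
    def test_top_concentrated_set_has_high_positive_es(self):
        import pandas as pd
        scores = pd.Series(np.linspace(3, -3, 20),
                           index=[f"G{i+1}" for i in range(20)])
        recs = gsea_preranked(scores, {"top": ["G1", "G2", "G3", "G4", "G5"]},
                              weight=0.0, n_perm=200, seed=1)
        assert recs[0].es > 0.7

    def test_random_half_has_mean_es_near_zero(self, rng):
        import pandas as pd
        scores = pd.Series(np.linspace(2, -2, 30),
                           index=[f"G{i+1}" for i in range(30)])
        ess = []
        for s in range(30):
            srng = np.random.default_rng(s)
            members = [f"G{i+1}" for i in srng.choice(30, 15, replace=False)]
            recs = gsea_preranked(scores, {"half": members}, weight=0.0,
                                  n_perm=50, seed=s)
            ess.append(recs[0].es)
        assert abs(np.mean(ess)) < 0.1

    def test_exhaustive_enumeration_p_on_six_genes(self):
        """With C(6,2)=15 possible draws the permutation p must equal the
        exact enumeration probability."""
        import pandas as pd
        scores = pd.Series([2.0, 1.0, 0.5, -0.5, -1.0, -2.0],
                           index=list("ABCDEF"))
        genesets = {"pair": ["A", "B"]}
        recs = gsea_preranked(scores, genesets, weight=1.0, n_perm=1000,
                              seed=0, min_size=2)
        es_obs = recs[0].es
        null = [_es_oracle(c, scores.to_numpy(), 1.0, 2)
                for c in itertools.combinations(range(6), 2)]
        same_sign = [e for e in null if np.sign(e) == np.sign(es_obs)]
        p_exact = sum(abs(e) >= abs(es_obs) for e in same_sign) / 15
        assert recs[0].pvalue == pytest.approx(p_exact)
        assert es_obs == pytest.approx(
            _es_oracle((0, 1), scores.to_numpy(), 1.0, 2))

    def test_es_within_bounds_and_reversal_negates(self, rng):
        import pandas as pd
        vals = np.sort(rng.normal(0, 1, 40))[::-1]
        idx = [f"G{i+1}" for i in range(40)]
        scores = pd.Series(vals, index=idx)
        members = [f"G{i+1}" for i in rng.choice(40, 8, replace=False)]
        fwd = gsea_preranked(scores, {"s": members}, weight=0.0, n_perm=50,
                             seed=3)[0]
        rev_scores = pd.Series(-vals[::-1], index=idx[::-1])
        rev = gsea_preranked(rev_scores, {"s": members}, weight=0.0,
                             n_perm=50, seed=3)[0]
        assert -1 <= fwd.es <= 1
        assert fwd.es == pytest.approx(-rev.es)
        assert np.sign(fwd.nes) == np.sign(fwd.es)

    def test_undersized_or_oversized_sets_skipped(self):
        import pandas as pd
        scores = pd.Series([1.0, 0.5, -0.5], index=["A", "B", "C"])
        recs = gsea_preranked(scores, {"tiny": ["A"],
                                       "everything": ["A", "B", "C"]},
                              min_size=2)
        assert recs == []


class TestSimulatedExpression:
    def test_spike_recovery_and_enrichment(self):
        x, truth = simulate_expression(ExprSimConfig(
            g_genes=300, n_spiked=6, spike_log2fc=2.0, noise_sd=0.4,
            enriched_set_size=20, enrichment_shift=0.8, seed=5))
        recs = differential_expression(x)
        sig = {r.gene_id for r in recs if r.significant}
        assert sig == set(truth["spiked_genes"])
        ranking = sorted(recs, key=lambda r: r.log2fc, reverse=True)
        import pandas as pd
        series = pd.Series([r.log2fc for r in ranking],
                           index=[r.gene_id for r in ranking])
        out = gsea_preranked(series, {"enriched": truth["enriched_set"]},
                             n_perm=200, seed=1)
        assert out[0].es > 0
        assert out[0].pvalue < 0.05

    def test_correlated_pair_recovered(self):
        x, truth = simulate_expression(ExprSimConfig(
            g_genes=50, s_per_group=(100, 100),
            corr_pairs=[(4, 9, 0.9)], seed=8))
        a, b, r = truth["corr_pairs"][0]
        res = gene_correlation(x, a, [b])[0]
        assert res.r == pytest.approx(0.9, abs=0.1)

    def test_round_trip_tsv(self, tmp_path, rng):
        x = matrix(rng.normal(5, 1, (5, 8)))
        write_expression_tsv(x, tmp_path / "e.tsv", tmp_path / "g.tsv")
        back = read_expression_tsv(tmp_path / "e.tsv", tmp_path / "g.tsv")
        np.testing.assert_allclose(back.values, x.values)
        assert back.groups == x.groups

    def test_read_gmt(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("SET1\tdesc\tG1\tG2\tG3\nSET2\tdesc\tG4\tG5\n")
        sets = read_gmt(gmt)
        assert sets == {"SET1": ["G1", "G2", "G3"], "SET2": ["G4", "G5"]}
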