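"""Instrument selection: cis window, FDR, LD clumping, F-statistic."""

import numpy as np
import pytest

from mrscreen import (GeneRegion, LDMatrix, SelectionConfig,
                      benjamini_hochberg, clump, f_statistic, filter_cis,
                      select_instruments)
from mrscreen.selection import filter_f, filter_significance

from conftest import make_table

REGION = GeneRegion("GENE", "1", 10_000, 20_000)


class TestCisFilter:
    @pytest.mark.parametrize("pos, kept", [
        (10_000, True),       # gene start
        (20_000, True),       # gene end
        (5_000, True),        # exactly window_bp upstream (inclusive)
        (25_000, True),       # exactly window_bp downstream
        (4_999, False),
        (25_001, False),
    ])
    def test_window_boundaries_inclusive(self, pos, kept):
        table = make_table([{"snp": "rs1", "pos": pos}])
        out = filter_cis(table, REGION, window_bp=5000)
        assert (len(out) == 1) is kept

    def test_other_chromosome_removed(self):
        table = make_table([{"snp": "rs1", "chrom": "2", "pos": 10_000}])
        assert len(filter_cis(table, REGION, 5000)) == 0


def _bh_oracle(p):
    """Step-up rule, written directly: adj_(i) = min_{k>=i} p_(k)·m/k."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 7), [0.2] * 7)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=rng.integers(2, 40))
        np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p),
                                   atol=1e-12)

    def test_out_of_range_is_fatal(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 0.0])
        with pytest.raises(ValueError):
            benjamini_hochberg([1.2])


class TestFilterSignificance:
    def test_all_null_gives_empty(self):
        table = make_table([{"snp": f"rs{i}", "pvalue": 0.5}
                            for i in range(4)])
        assert len(filter_significance(table, SelectionConfig())) == 0

    def test_bh_example_all_survive(self):
        table = make_table([
            {"snp": f"rs{i}", "pvalue": p}
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ])
        out = filter_significance(table, SelectionConfig(fdr_threshold=0.05))
        assert len(out) == 4  # adjusted 0.04 < 0.05

    def test_reverse_mode_uses_raw_threshold(self):
        table = make_table([{"snp": "rs1", "pvalue": 4e-8},
                            {"snp": "rs2", "pvalue": 6e-8}])
        out = filter_significance(
            table, SelectionConfig(pvalue_threshold=5e-8))
        assert list(out.df["snp"]) == ["rs1"]

    def test_never_retains_raw_p_above_fdr_threshold(self, rng):
        p = rng.uniform(0, 1, 50)
        table = make_table([{"snp": f"rs{i}", "pvalue": pi}
                            for i, pi in enumerate(p)])
        cfg = SelectionConfig(fdr_threshold=0.1)
        out = filter_significance(table, cfg)
        assert (out.df["pvalue"] < 0.1).all()


def _clump_oracle(df, r, r2_threshold, window_bp):
    """Brute-force greedy clumping, written independently."""
    remaining = set(range(len(df)))
    kept = []
    while remaining:
        idx = min(remaining, key=lambda i: (df.loc[i, "pvalue"],
                                            df.loc[i, "pos"],
                                            df.loc[i, "snp"]))
        kept.append(idx)
        remaining.discard(idx)
        for j in list(remaining):
            if (df.loc[j, "chrom"] == df.loc[idx, "chrom"]
                    and abs(df.loc[j, "pos"] - df.loc[idx, "pos"]) <= window_bp
                    and r[idx, j] ** 2 > r2_threshold):
                remaining.discard(j)
    return {df.loc[i, "snp"] for i in kept}


def _random_instance(seed, m=10):
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, (m, m))
    r = (a + a.T) / 2
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1, 1)
    table = make_table([
        {"snp": f"rs{i + 1}", "pos": int(rng.integers(1, 50_000)),
         "pvalue": float(rng.uniform(1e-8, 1))}
        for i in range(m)
    ])
    ld = LDMatrix(list(table.df["snp"]), r)
    return table, ld, r


class TestClump:
    def test_identity_ld_keeps_everything(self):
        table, _, _ = _random_instance(0)
        ld = LDMatrix(list(table.df["snp"]), np.eye(10))
        assert len(clump(table, ld)) == 10

    def test_perfect_proxy_pruned(self):
        table = make_table([
            {"snp": "rs1", "pos": 1000, "pvalue": 1e-10},
            {"snp": "rs2", "pos": 2000, "pvalue": 1e-4},
        ])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        out = clump(table, ld, r2_threshold=0.1, window_kb=10)
        assert list(out.df["snp"]) == ["rs1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        table, ld, r = _random_instance(seed)
        got = set(clump(table, ld, 0.2, 100).df["snp"])
        assert got == _clump_oracle(table.df, r, 0.2, 100_000)

    def test_row_order_does_not_matter(self):
        table, ld, _ = _random_instance(4)
        shuffled = table.df.sample(frac=1, random_state=1).reset_index(drop=True)
        from mrscreen.sumstats import AssociationTable
        out1 = clump(table, ld, 0.2, 100)
        out2 = clump(AssociationTable(shuffled), ld, 0.2, 100)
        assert list(out1.df["snp"]) == list(out2.df["snp"])

    def test_output_is_independent_set(self):
        table, ld, r = _random_instance(7)
        out = clump(table, ld, 0.2, 100)
        idx = {s: i for i, s in enumerate(table.df["snp"])}
        kept = list(out.df["snp"])
        pos = table.df.set_index("snp")["pos"]
        for a in kept:
            for b in kept:
                if a != b and abs(pos[a] - pos[b]) <= 100_000:
                    assert r[idx[a], idx[b]] ** 2 <= 0.2

    def test_missing_pairs_unlinked_or_strict_error(self):
        table = make_table([
            {"snp": "rs1", "pos": 1000, "pvalue": 1e-10},
            {"snp": "rsX", "pos": 1500, "pvalue": 1e-4},
        ])
        ld = LDMatrix(["rs1"], np.array([[1.0]]))
        assert len(clump(table, ld)) == 2
        with pytest.raises(ValueError, match="missing"):
            clump(table, ld, strict=True)


class TestFStatistic:
    def test_analytic_values(self):
        assert f_statistic(0.1, 0.1) == pytest.approx(1.0)
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)

    def test_threshold_is_strict(self):
        # F exactly at the threshold is excluded (strict inequality);
        # use an exactly representable F = (0.2/0.1)^2 = 4
        table = make_table([{"snp": "rs1", "beta": 0.2, "se": 0.1},
                            {"snp": "rs2", "beta": 0.1, "se": 0.02}])
        out = filter_f(table, f_min=4)
        assert list(out.df["snp"]) == ["rs2"]

    def test_nonpositive_se_fatal(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


def test_selection_pipeline_order_applies_all_gates():
    # 3 significant SNPs in one LD clump inside the cis window, one weak,
    # one outside the window, one nonsignificant
    table = make_table([
        {"snp": "rs1", "pos": 12_000, "pvalue": 1e-12, "beta": 0.2,
         "se": 0.01},
        {"snp": "rs2", "pos": 12_500, "pvalue": 1e-6, "beta": 0.15,
         "se": 0.01},
        {"snp": "rs3", "pos": 18_000, "pvalue": 1e-8, "beta": 0.02,
         "se": 0.01},  # F = 4: weak
        {"snp": "rs4", "pos": 90_000, "pvalue": 1e-12, "beta": 0.2,
         "se": 0.01},  # outside cis window
        {"snp": "rs5", "pos": 13_000, "pvalue": 0.9, "beta": 0.1,
         "se": 0.01},
    ])
    r = np.eye(5)
    r[0, 1] = r[1, 0] = 0.9
    ld = LDMatrix([f"rs{i + 1}" for i in range(5)], r)
    out = select_instruments(table, ld, SelectionConfig(), region=REGION)
    assert list(out.df["snp"]) == ["rs1"]
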