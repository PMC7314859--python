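"""Beta-binomial Wald test, BH FDR, tile/DMR calling, category fractions."""

import numpy as np
import pandas as pd
import pytest

from strainmeth.calls import CpGCountTable
from strainmeth.diff import (
    Dmr,
    TestParams,
    bh_fdr,
    call_dmrs,
    call_dmts,
    chromosome_log2fc,
    dml_test,
    methylation_categories,
    tile_counts,
)


def _table(meth, unmeth, pos=None, chrom="chr1", sample="s"):
    meth = np.asarray(meth)
    pos = np.arange(len(meth)) * 50 if pos is None else np.asarray(pos)
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "unmeth": unmeth})
    return CpGCountTable(df, sample)


def _bb_tables(rng, p, phi, cov, nrep, label, pos=None):
    out = []
    for i in range(nrep):
        n = rng.poisson(cov, size=len(p)).clip(min=1)
        if phi > 0:
            a = p * (1 / phi - 1)
            b = (1 - p) * (1 / phi - 1)
            x = rng.binomial(n, rng.beta(a, b))
        else:
            x = rng.binomial(n, p)
        out.append(_table(x, n - x, pos=pos, sample=f"{label}{i}"))
    return out


class TestBhFdr:
    def test_worked_step_up_triple(self):
        # p=[.01,.02,.03], m=3: q_i = min over j>=i of p_(j)*3/j = .03 for all
        assert bh_fdr(np.array([0.01, 0.02, 0.03])).tolist() == [0.03, 0.03, 0.03]

    def test_all_ones(self):
        assert bh_fdr(np.ones(4)).tolist() == [1.0] * 4

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2])).tolist() == [0.2]

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), q_ref)


class TestDmlTest:
    def test_identical_tables_give_null_result(self):
        t = _table([5, 8, 2], [5, 2, 8])
        res = dml_test([t], [t], smooth_span=0)
        assert (res["diff"] == 0).all()
        assert (res["pval"] == 1).all()
        assert (res["stat"] == 0).all()

    def test_wald_arithmetic_oracle(self):
        """A: 95/100 vs B: 5/100 with phi -> 0 gives z ~= 29.2.

        var = p(1-p)/n = 0.95*0.05/100 = 0.000475 per group;
        z = 0.9 / sqrt(2 * 0.000475) = 29.19.
        """
        a = _table([95], [5])
        b = _table([5], [95])
        res = dml_test([a], [b], smooth_span=0)
        assert res.loc[0, "diff"] == pytest.approx(0.9)
        assert res.loc[0, "stat"] == pytest.approx(0.9 / np.sqrt(2 * 0.000475), rel=1e-6)
        assert res.loc[0, "pval"] < 1e-5

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, 500)
        A = _bb_tables(rng, p, 0.01, 30, 2, "a")
        B = _bb_tables(rng, np.clip(p + 0.1, 0, 1), 0.01, 30, 2, "b")
        fwd = dml_test(A, B, smooth_span=0)
        rev = dml_test(B, A, smooth_span=0)
        assert np.allclose(fwd["diff"], -rev["diff"])
        assert np.allclose(fwd["stat"], -rev["stat"])
        assert np.allclose(fwd["pval"], rev["pval"])

    def test_null_calibration_single_seed(self):
        """Fraction of p < 0.05 under the null near nominal (locked from a
        5-seed Monte-Carlo calibration of the dispersion estimator)."""
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 20_000)
        A = _bb_tables(rng, p, 0.01, 30, 2, "a")
        B = _bb_tables(rng, p, 0.01, 30, 2, "b")
        res = dml_test(A, B, smooth_span=0)
        assert 0.04 <= (res["pval"] < 0.05).mean() <= 0.06

    def test_power_at_planted_difference(self):
        """d = 0.4 at pooled coverage >= 20 per group: >= 70% detected at
        q < 0.01 (frozen regression bound from calibration)."""
        rng = np.random.default_rng(7)
        n_sites = 2000
        p_wt = np.full(n_sites, 0.7)
        A = _bb_tables(rng, p_wt, 0.01, 20, 2, "a")
        B = _bb_tables(rng, p_wt - 0.4, 0.01, 20, 2, "b")
        res = dml_test(A, B, smooth_span=0)
        assert (res["qval"] < 0.01).mean() >= 0.70

    def test_single_replicate_uses_local_dispersion(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.3, 0.7, 1000)
        A = _bb_tables(rng, p, 0.01, 30, 1, "a")
        B = _bb_tables(rng, p, 0.01, 30, 1, "b")
        res = dml_test(A, B, smooth_span=500)
        assert (res["phi1"] > 0).any()
        assert (res["pval"] < 0.05).mean() < 0.12

    def test_no_common_sites_warns_and_returns_empty(self, caplog):
        a = _table([5], [5], pos=[100])
        b = _table([5], [5], pos=[900])
        res = dml_test([a], [b])
        assert res.empty


class TestTiles:
    def test_tile_partition_is_exhaustive_and_disjoint(self):
        """Every position belongs to exactly tile floor(pos/1000)."""
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(10_000, size=500, replace=False))
        t = _table(rng.integers(0, 5, len(pos)), rng.integers(1, 5, len(pos)), pos=pos)
        tiled = tile_counts(t, 1000)
        expected = {(p // 1000) * 1000 for p in pos}
        assert set(tiled.df["pos"]) == expected
        # counts conserved
        assert tiled.total_calls() == t.total_calls()

    def test_tile_below_min_coverage_ineligible(self):
        wt = _table([5, 5], [4, 5], pos=[100, 1100])  # tile 0: cov 9 -> ineligible
        ko = _table([10, 10], [10, 10], pos=[100, 1100])
        res = call_dmts([wt], [ko], TestParams())
        row0 = res[res["pos"] == 0].iloc[0]
        row1 = res[res["pos"] == 1000].iloc[0]
        assert not row0["eligible"]
        assert row1["eligible"]

    def test_planted_tiles_called_and_weak_tiles_never(self):
        """WT-KO = 0.5 tiles pass FDR<0.01 & diff>0.4; 0.3 tiles never do.

        Tiles carry 20 CpG sites each, so pooled tile coverage is far above
        the 10x eligibility floor, as in real 1-kb tiles.
        """
        rng = np.random.default_rng(11)
        n_tiles, sites_per_tile = 150, 20
        tile_of_site = np.repeat(np.arange(n_tiles), sites_per_tile)
        pos = tile_of_site * 1000 + np.tile(np.arange(sites_per_tile) * 50, n_tiles)
        p_wt = np.full(len(pos), 0.8)
        p_ko = p_wt.copy()
        strong = np.arange(0, 40)
        weak = np.arange(40, 80)
        p_ko[np.isin(tile_of_site, strong)] -= 0.5
        p_ko[np.isin(tile_of_site, weak)] -= 0.3
        wt = _bb_tables(rng, p_wt, 0.005, 15, 2, "wt", pos=pos)
        ko = _bb_tables(rng, p_ko, 0.005, 15, 2, "ko", pos=pos)
        res = call_dmts(wt, ko, TestParams())
        called = set((res.loc[res["dmt"], "pos"] // 1000).tolist())
        assert called & set(weak.tolist()) == set()
        recall = len(called & set(strong.tolist())) / len(strong)
        precision = len(called & set(strong.tolist())) / max(len(called), 1)
        assert recall >= 0.9 and precision >= 0.9


class TestDmrs:
    def _records(self, pos, pval, diff, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": pos, "mu1": 0.8, "mu2": 0.8 - np.asarray(diff),
             "diff": diff, "phi1": 0.0, "phi2": 0.0, "stat": 5.0,
             "pval": pval, "qval": pval}
        )

    def test_run_construction_oracle(self):
        """12 consecutive significant sites 20 bp apart form one DMR."""
        pos = np.arange(12) * 20
        rec = self._records(pos, [1e-7] * 12, [0.5] * 12)
        dmrs = call_dmrs(rec, TestParams())
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.n_cg == 12 and d.direction == "WT_gt_KO"
        assert (d.start, d.end) == (0, 222)

    def test_nine_sites_below_min_cg(self):
        pos = np.arange(9) * 20
        rec = self._records(pos, [1e-7] * 9, [0.5] * 9)
        assert call_dmrs(rec, TestParams()) == []

    def test_small_mean_difference_rejected(self):
        pos = np.arange(15) * 20
        rec = self._records(pos, [1e-7] * 15, [0.15] * 15)
        assert call_dmrs(rec, TestParams()) == []

    def test_gap_splits_regions(self):
        pos = np.concatenate([np.arange(12) * 20, 1000 + np.arange(12) * 20])
        rec = self._records(pos, [1e-7] * 24, [0.5] * 24)
        dmrs = call_dmrs(rec, TestParams())
        assert len(dmrs) == 2

    def test_unsorted_input_is_contract_error(self):
        rec = self._records([40, 20, 0], [1e-7] * 3, [0.5] * 3)
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(rec, TestParams())

    def test_null_data_produces_no_dmrs(self):
        """At p.threshold 1e-5 the expected seed count on a null genome is
        far below 1; across 5 seeds no DMR may appear."""
        params = TestParams()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.2, 0.8, 5000)
            A = _bb_tables(rng, p, 0.01, 50, 2, "a")
            B = _bb_tables(rng, p, 0.01, 50, 2, "b")
            res = dml_test(A, B, smooth_span=0)
            assert call_dmrs(res, params) == []


class TestCategoriesAndLog2FC:
    def test_example_fractions(self):
        t = _table([9, 5, 1], [1, 5, 9])  # levels .9, .5, .1
        assert methylation_categories(t) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_boundary_point_eight_is_intermediate(self):
        t = _table([8], [2])
        assert methylation_categories(t) == (0.0, 1.0, 0.0)

    def test_all_fully_methylated(self):
        t = _table([5, 5], [0, 0])
        assert methylation_categories(t) == (1.0, 0.0, 0.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(0, 20, 300), rng.integers(0, 20, 300) + 1)
        assert sum(methylation_categories(t)) == pytest.approx(1.0)

    def test_empty_table_is_error(self):
        t = _table([], [])
        with pytest.raises(ValueError):
            methylation_categories(t)

    def test_log2fc_self_is_zero(self):
        rng = np.random.default_rng(9)
        t = _table(rng.integers(1, 20, 200), rng.integers(1, 20, 200))
        fc = chromosome_log2fc(t, t)
        assert fc["chr1"] == 0.0

    def test_log2fc_halved_methylation(self):
        n = 150
        wt = _table([8] * n, [2] * n)
        ko = _table([4] * n, [6] * n)
        fc = chromosome_log2fc(ko, wt)
        assert fc["chr1"] == pytest.approx(-1.0)

    def test_log2fc_too_few_shared_sites_is_missing(self):
        wt = _table([8] * 10, [2] * 10)
        ko = _table([4] * 10, [6] * 10)
        assert chromosome_log2fc(ko, wt, min_shared_sites=100)["chr1"] is None
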