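"""Region summaries, target genes, distribution comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

from strainmeth.calls import CpGCountTable
from strainmeth.diff import Dmr
from strainmeth.features import (
    GeneAnnotation,
    cgi_split,
    compare_groups,
    expressed_promoter_filter,
    gene_summaries,
    identify_target_genes,
    region_mean,
    threshold_diff_genes,
)


def _table(rows, sample="s"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    return CpGCountTable(df, sample)


def _annotation(genes=None, cgis=None):
    genes = pd.DataFrame(
        genes or [("g1", "chr1", "+", 5000, 9000, True)],
        columns=["gene_id", "chrom", "strand", "tss", "tes", "is_pcg"],
    )
    cgis = pd.DataFrame(cgis or [], columns=["chrom", "start", "end", "label"])
    return GeneAnnotation(genes, cgis)


class TestRegionMean:
    def _sites(self):
        return _table([
            ("chr1", 100, 2, 8),   # 0.2
            ("chr1", 200, 4, 6),   # 0.4
            ("chr1", 300, 6, 4),   # 0.6
        ])

    def test_unweighted_mean(self):
        intervals = pd.DataFrame(
            [("r", "chr1", 0, 400)], columns=["region_id", "chrom", "start", "end"]
        )
        res = region_mean(self._sites(), intervals, min_cov=5, min_sites=3)
        assert res.loc[0, "mean"] == pytest.approx(0.4)

    def test_below_min_sites_is_missing(self):
        intervals = pd.DataFrame(
            [("r", "chr1", 0, 250)], columns=["region_id", "chrom", "start", "end"]
        )
        res = region_mean(self._sites(), intervals, min_cov=5, min_sites=3)
        assert np.isnan(res.loc[0, "mean"])
        assert res.loc[0, "n_sites"] == 2

    def test_no_cpg_interval_is_missing(self):
        intervals = pd.DataFrame(
            [("r", "chr1", 5000, 6000)], columns=["region_id", "chrom", "start", "end"]
        )
        res = region_mean(self._sites(), intervals)
        assert np.isnan(res.loc[0, "mean"])

    def test_subdivision_recombination_invariance(self):
        """Mean over an interval equals the site-count-weighted recombination
        of its halves."""
        rng = np.random.default_rng(0)
        rows = [("chr1", int(p), int(m), int(u))
                for p, m, u in zip(sorted(rng.choice(10_000, 200, replace=False)),
                                   rng.integers(0, 20, 200), rng.integers(1, 20, 200))]
        table = _table(rows)
        whole = pd.DataFrame([("w", "chr1", 0, 10_000)],
                             columns=["region_id", "chrom", "start", "end"])
        halves = pd.DataFrame([("a", "chr1", 0, 5_000), ("b", "chr1", 5_000, 10_000)],
                              columns=["region_id", "chrom", "start", "end"])
        rw = region_mean(table, whole, min_cov=1, min_sites=1)
        rh = region_mean(table, halves, min_cov=1, min_sites=1)
        weighted = (rh["mean"] * rh["n_sites"]).sum() / rh["n_sites"].sum()
        assert rw.loc[0, "mean"] == pytest.approx(weighted)


class TestGeneSummaries:
    def test_plus_strand_promoter_interval(self):
        table = _table([("chr1", p, 5, 5) for p in (4100, 4500, 5900)])
        res = gene_summaries(table, _annotation(), min_cov=5, min_sites=3)
        tss = res["tss"]
        assert (tss.loc[0, "start"], tss.loc[0, "end"]) == (4000, 6000)
        assert tss.loc[0, "mean"] == pytest.approx(0.5)

    def test_minus_strand_tss_is_rightmost(self):
        ann = _annotation(genes=[("g1", "chr1", "-", 9000, 5000, False)])
        table = _table([("chr1", p, 5, 5) for p in (8100, 8500, 9900)])
        res = gene_summaries(table, ann, min_cov=5, min_sites=3)
        assert (res["tss"].loc[0, "start"], res["tss"].loc[0, "end"]) == (8000, 10000)
        assert (res["body"].loc[0, "start"], res["body"].loc[0, "end"]) == (5000, 9000)

    def test_gene_without_covered_cpgs_missing(self):
        res = gene_summaries(_table([("chr1", 100, 5, 5)]), _annotation())
        assert np.isnan(res["tss"].loc[0, "mean"])
        assert np.isnan(res["body"].loc[0, "mean"])


class TestTargetGenes:
    def test_wt_gt_ko_dmr_in_body_lists_gene(self):
        dmr = Dmr("chr1", 6000, 6500, 12, 0.5, "WT_gt_KO", 1.0)
        assert identify_target_genes([dmr], _annotation()) == ["g1"]

    def test_opposite_direction_not_listed(self):
        dmr = Dmr("chr1", 6000, 6500, 12, -0.5, "KO_gt_WT", 1.0)
        assert identify_target_genes([dmr], _annotation()) == []

    def test_intergenic_dmr_contributes_nothing(self):
        dmr = Dmr("chr1", 50_000, 50_500, 12, 0.5, "WT_gt_KO", 1.0)
        assert identify_target_genes([dmr], _annotation()) == []

    def test_promoter_overlap_counts(self):
        # gene extent includes TSS-1000: DMR at [4100, 4300) overlaps
        dmr = Dmr("chr1", 4100, 4300, 12, 0.5, "WT_gt_KO", 1.0)
        assert identify_target_genes([dmr], _annotation()) == ["g1"]


class TestThresholdDiffGenes:
    def _summary(self, means):
        return pd.DataFrame(
            {"region_id": [f"g{i}" for i in range(len(means))], "mean": means}
        )

    def test_thresholding(self):
        a = self._summary([0.50, 0.50, 0.50])
        b = self._summary([0.38, 0.41, 0.62])
        res = threshold_diff_genes(a, b, min_abs_diff=0.1)
        assert res["region_id"].tolist() == ["g0", "g2"]
        assert res["direction"].tolist() == ["A_gt_B", "B_gt_A"]

    def test_gene_missing_in_one_summary_excluded(self):
        a = self._summary([0.5, 0.5])
        b = self._summary([0.1, np.nan])
        res = threshold_diff_genes(a, b)
        assert res["region_id"].tolist() == ["g0"]


class TestCgiSplit:
    def _setup(self):
        cgis = [("chrX", 100, 300, "cgi1")]
        genes = [("g1", "chrX", "+", 5000, 9000, False),
                 ("g2", "chr1", "+", 5000, 9000, False)]
        ann = _annotation(genes=genes, cgis=cgis)
        table = _table([
            ("chrX", 150, 1, 9),
            ("chrX", 400, 9, 1),
            ("chr1", 150, 9, 1),
        ])
        return ann, table

    def test_partition_on_x(self):
        ann, table = self._setup()
        cgi, non = cgi_split(table, ann, chromosome_filter="X", min_cov=5)
        assert cgi.tolist() == [0.1]
        assert non.tolist() == [0.9]

    def test_autosomal_site_excluded_by_x_filter(self):
        ann, table = self._setup()
        cgi, non = cgi_split(table, ann, chromosome_filter="X", min_cov=5)
        assert len(cgi) + len(non) == 2  # chr1 site dropped

    def test_partition_is_exhaustive_and_disjoint(self):
        ann, table = self._setup()
        cgi, non = cgi_split(table, ann, chromosome_filter=None, min_cov=5)
        assert len(cgi) + len(non) == 3

    def test_unknown_filter_is_error(self):
        ann, table = self._setup()
        with pytest.raises(ValueError):
            cgi_split(table, ann, chromosome_filter="chr99")


def _mwu_enumeration(a, b):
    """Exact two-sided MWU p-value by complete enumeration of labelings."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(sample_a, sample_b):
        return sum((x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b)

    observed = u_stat(a, b)
    n_extreme = total = 0
    mean_u = len(a) * len(b) / 2
    for combo in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            n_extreme += 1
    return n_extreme / total


def _wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    observed = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    n_extreme = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
            n_extreme += 1
    return n_extreme / total


class TestCompareGroups:
    def test_identical_samples_ks_d_zero(self):
        stat, p = compare_groups([1, 2, 3], [1, 2, 3], "ks_two_sample")
        assert stat == 0.0

    def test_mwu_separated_triples(self):
        """U = 0 for A, exact one-sided 1/20 -> two-sided 0.1."""
        stat, p = compare_groups([1, 2, 3], [4, 5, 6], "mann_whitney")
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_mwu_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 5))
        nb = int(rng.integers(2, 9 - na))
        vals = rng.choice(100, size=na + nb, replace=False).astype(float)
        a, b = vals[:na], vals[na:]
        _, p = compare_groups(a, b, "mann_whitney")
        assert p == pytest.approx(_mwu_enumeration(a, b))

    @pytest.mark.parametrize("seed", range(6))
    def test_wilcoxon_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        diffs = rng.choice(np.arange(1, 50), size=n, replace=False).astype(float)
        diffs *= rng.choice([-1, 1], size=n)
        a = diffs
        b = np.zeros(n)
        _, p = compare_groups(a, b, "wilcoxon_signed_rank", paired=True)
        assert p == pytest.approx(_wilcoxon_enumeration(diffs))

    def test_wilcoxon_all_zero_differences(self):
        stat, p = compare_groups([1.0, 2.0], [1.0, 2.0], "wilcoxon_signed_rank", paired=True)
        assert p == 1.0

    def test_paired_test_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 2], "wilcoxon_signed_rank", paired=True)


class TestExpressedPromoterFilter:
    def _tss(self, means):
        return pd.DataFrame({
            "region_id": [f"g{i}" for i in range(len(means))],
            "chrom": "chr1", "start": 0, "end": 2000,
            "mean": means, "n_sites": 5,
        })

    def test_strictly_greater_than_threshold(self):
        tss = self._tss([0.16, 0.15, 0.14])
        expr = pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "fpkm": [1.0, 2.0, 3.0]})
        res = expressed_promoter_filter(tss, expr, min_tss_meth=0.15)
        assert res["region_id"].tolist() == ["g0"]

    def test_gene_absent_from_expression_kept_with_blank(self):
        tss = self._tss([0.3])
        expr = pd.DataFrame({"gene_id": ["other"], "fpkm": [1.0]})
        res = expressed_promoter_filter(tss, expr)
        assert res["region_id"].tolist() == ["g0"]
        assert np.isnan(res.loc[0, "fpkm"])
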