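"""Gene/CGI/repeat annotations and region-level methylation summaries.

Summaries mirror the figure-level statistics of an allele-aware methylome
study: promoter (TSS +/- 1 kb) and gene-body mean methylation, target-gene
identification from hypomethylated DMRs, CGI vs non-CGI site-level
distributions on a chromosome class (e.g. the X), and two-sample
distribution tests (KS, Mann-Whitney, Wilcoxon signed-rank).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from strainmeth.calls import CpGCountTable
from strainmeth.diff import Dmr, WT_GT_KO
from strainmeth.genome import classify_chromosome

logger = logging.getLogger(__name__)

_GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes", "is_pcg"]
_INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass
class GeneAnnotation:
    """Genes (with TSS/TES and a PcG-target flag), CGIs and repeat intervals.

    ``tss``/``tes`` are strand-oriented: on the minus strand the TSS is the
    rightmost coordinate.  Intervals are 0-based half-open.
    """

    genes: pd.DataFrame
    cgis: pd.DataFrame
    repeats: pd.DataFrame = None
    chrom_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if self.repeats is None:
            self.repeats = pd.DataFrame(columns=_INTERVAL_COLUMNS + ["label"])
        bad = self.genes[
            ((self.genes["strand"] == "+") & (self.genes["tss"] > self.genes["tes"]))
            | ((self.genes["strand"] == "-") & (self.genes["tss"] < self.genes["tes"]))
        ]
        if len(bad):
            raise ValueError(f"TSS/TES orientation inconsistent with strand for {list(bad['gene_id'])}")
        for name in pd.unique(self.genes["chrom"]):
            self.chrom_class.setdefault(name, classify_chromosome(name))

    def pcg_gene_ids(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["is_pcg"], "gene_id"])

    def gene_extent(self, row, promoter: int = 1000) -> tuple[int, int]:
        """[TSS - promoter, TES] span in genome coordinates (strand-aware)."""
        if row.strand == "+":
            return row.tss - promoter, row.tes
        return row.tes, row.tss + promoter


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Load BED (>=3 columns) as an interval table; extra columns kept as label."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            label = fields[3] if len(fields) > 3 else "."
            rows.append((fields[0], int(fields[1]), int(fields[2]), label))
    return pd.DataFrame(rows, columns=_INTERVAL_COLUMNS + ["label"])


def write_bed_intervals(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "label") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Genes as TSV: gene_id, chrom, strand, tss, tes, is_pcg (0/1)."""
    df = pd.read_csv(path, sep="\t")
    df["is_pcg"] = df["is_pcg"].astype(bool)
    return df[_GENE_COLUMNS]


def read_gene_set(path: str | Path) -> set[str]:
    with open(path) as handle:
        return {line.strip() for line in handle if line.strip()}


def _site_levels(table: CpGCountTable, min_cov: int) -> pd.DataFrame:
    t = table.filter(min_cov)
    df = t.df.copy()
    df["level"] = df["meth"] / (df["meth"] + df["unmeth"])
    return df


def region_mean(
    table: CpGCountTable,
    intervals: pd.DataFrame,
    min_cov: int = 5,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Unweighted mean of per-site levels inside each interval.

    ``intervals`` needs columns ``region_id, chrom, start, end`` (0-based
    half-open).  Regions with fewer than ``min_sites`` qualifying sites get
    a missing mean, not a noisy one.
    """
    sites = _site_levels(table, min_cov)
    by_chrom = {c: sub.sort_values("pos") for c, sub in sites.groupby("chrom", sort=False)}
    rows = []
    for row in intervals.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None:
            rows.append((row.region_id, row.chrom, row.start, row.end, np.nan, 0))
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.end, side="left")
        n = hi - lo
        mean = float(sub["level"].to_numpy()[lo:hi].mean()) if n >= min_sites else np.nan
        rows.append((row.region_id, row.chrom, row.start, row.end, mean, int(n)))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "mean", "n_sites"])


def gene_summaries(
    table: CpGCountTable,
    annotation: GeneAnnotation,
    promoter_halfwidth: int = 1000,
    min_cov: int = 5,
    min_sites: int = 3,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-gene promoter (TSS +/- 1 kb) and gene-body mean methylation."""
    tss_rows, body_rows = [], []
    for g in annotation.genes.itertuples():
        t_lo, t_hi = g.tss - promoter_halfwidth, g.tss + promoter_halfwidth
        b_lo, b_hi = min(g.tss, g.tes), max(g.tss, g.tes)
        if chrom_lengths and g.chrom in chrom_lengths:
            L = chrom_lengths[g.chrom]
            if t_lo < 0 or t_hi > L or b_hi > L:
                logger.warning("gene %s extends beyond %s; clipped", g.gene_id, g.chrom)
            t_lo, t_hi = max(0, t_lo), min(L, t_hi)
            b_lo, b_hi = max(0, b_lo), min(L, b_hi)
        tss_rows.append((g.gene_id, g.chrom, t_lo, t_hi))
        body_rows.append((g.gene_id, g.chrom, b_lo, b_hi))
    cols = ["region_id", "chrom", "start", "end"]
    return {
        "tss": region_mean(table, pd.DataFrame(tss_rows, columns=cols), min_cov, min_sites),
        "body": region_mean(table, pd.DataFrame(body_rows, columns=cols), min_cov, min_sites),
    }


def identify_target_genes(
    dmrs: list[Dmr],
    annotation: GeneAnnotation,
    direction: str = WT_GT_KO,
    promoter: int = 1000,
) -> list[str]:
    """Genes overlapped (>=1 bp of [TSS - 1 kb, TES]) by a DMR of the given
    direction; the hypomethylated-in-KO direction defines de novo targets."""
    wanted = [d for d in dmrs if d.direction == direction]
    hits: set[str] = set()
    for g in annotation.genes.itertuples():
        lo, hi = annotation.gene_extent(g, promoter)
        for d in wanted:
            if d.chrom == g.chrom and d.start < hi and lo < d.end:
                hits.add(g.gene_id)
                break
    return sorted(hits)


def threshold_diff_genes(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    min_abs_diff: float = 0.1,
) -> pd.DataFrame:
    """Genes whose region means differ by at least ``min_abs_diff``.

    Returns ``region_id, mean_a, mean_b, diff, direction``; genes missing a
    defined mean in either summary are excluded.
    """
    merged = summary_a.merge(summary_b, on="region_id", suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["mean_a", "mean_b"])
    if merged.empty:
        logger.warning("threshold_diff_genes: no genes with defined means in both samples")
    merged["diff"] = merged["mean_a"] - merged["mean_b"]
    out = merged[np.abs(merged["diff"]) >= min_abs_diff].copy()
    out["direction"] = np.where(out["diff"] > 0, "A_gt_B", "B_gt_A")
    return out[["region_id", "mean_a", "mean_b", "diff", "direction"]].reset_index(drop=True)


def cgi_split(
    table: CpGCountTable,
    annotation: GeneAnnotation,
    chromosome_filter: str | None = None,
    min_cov: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition site levels into (CGI, non-CGI), optionally on one
    chromosome class ('autosome', 'X', ...) or a single chromosome name."""
    sites = _site_levels(table, min_cov)
    if chromosome_filter is not None:
        known_classes = {"autosome", "X", "Y", "MT"}
        if chromosome_filter in known_classes:
            keep_names = {
                name for name, cls in annotation.chrom_class.items() if cls == chromosome_filter
            }
            table_names = set(sites["chrom"])
            keep_names |= {n for n in table_names if classify_chromosome(n) == chromosome_filter}
        elif chromosome_filter in set(sites["chrom"]) | set(annotation.chrom_class):
            keep_names = {chromosome_filter}
        else:
            raise ValueError(f"unknown chromosome filter {chromosome_filter!r}")
        sites = sites[sites["chrom"].isin(keep_names)]
    in_cgi = np.zeros(len(sites), dtype=bool)
    pos_all = sites["pos"].to_numpy()
    for chrom, sub in annotation.cgis.groupby("chrom", sort=False):
        sel = (sites["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = sub["start"].sort_values().to_numpy()
        ends = sub.sort_values("start")["end"].to_numpy()
        idx = np.searchsorted(starts, pos_all[sel], side="right") - 1
        ok = (idx >= 0) & (pos_all[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        in_cgi[sel] = ok
    levels = sites["level"].to_numpy()
    return levels[in_cgi], levels[~in_cgi]


def compare_groups(
    values_a,
    values_b,
    test: str = "ks_two_sample",
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample comparison; exact computation at small n.

    ``ks_two_sample`` and ``mann_whitney`` are unpaired; ``wilcoxon_signed_rank``
    requires ``paired=True`` and equal lengths.  Exact null distributions are
    used when feasible (nA*nB <= 1e4 for KS/MWU, n <= 25 for Wilcoxon).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "wilcoxon_signed_rank":
        if not paired:
            raise ValueError("wilcoxon_signed_rank requires paired=True")
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.all(d == 0):
            logger.warning("compare_groups: all paired differences are zero; p=1")
            return 0.0, 1.0
        method = "exact" if len(d) <= 25 and not _has_zeros_or_tied_abs(d) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if paired:
        raise ValueError(f"{test} is an unpaired test")
    small = len(a) * len(b) <= 10_000
    if test == "ks_two_sample":
        res = stats.ks_2samp(a, b, alternative="two-sided", method="exact" if small else "asymp")
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if small and tie_free else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def _has_zeros_or_tied_abs(d: np.ndarray) -> bool:
    nz = d[d != 0]
    return len(nz) != len(d) or len(np.unique(np.abs(nz))) != len(nz)


def expressed_promoter_filter(
    tss_summary: pd.DataFrame,
    expression: pd.DataFrame,
    min_tss_meth: float = 0.15,
) -> pd.DataFrame:
    """Genes with promoter methylation strictly above ``min_tss_meth``,
    joined with an externally supplied FPKM table (columns gene_id, fpkm)."""
    known = set(tss_summary["region_id"])
    unknown = set(expression["gene_id"]) - known
    if unknown:
        logger.info("expressed_promoter_filter: %d expression ids not in annotation; skipped",
                    len(unknown))
    kept = tss_summary.dropna(subset=["mean"])
    kept = kept[kept["mean"] > min_tss_meth]
    out = kept.merge(
        expression[expression["gene_id"].isin(known)],
        left_on="region_id", right_on="gene_id", how="left",
    )
    out = out.rename(columns={"mean": "tss_mean"})
    return out[["region_id", "tss_mean", "fpkm"]].reset_index(drop=True)
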