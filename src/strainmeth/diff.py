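"""Two-group beta-binomial differential methylation testing.

The test at each locus (CpG site, or 1-kb tile treated as a pseudo-locus)
is a Wald test on the difference of pooled group methylation proportions.
Counts within a group are modelled beta-binomially: replicate i with
coverage n_i contributes variance n_i * p(1-p) * (1 + (n_i - 1) * phi) to
the pooled estimator, where phi is the group's dispersion.  phi is
estimated per locus by method of moments across replicates (or, with a
single replicate, from neighbouring loci within a smoothing window) and
shrunk 50:50 toward a stable genome-wide estimate.

Thresholds follow the analysis this package reproduces: differentially
methylated 1-kb tiles (DMTs) require FDR < 0.01 and a WT-KO difference
> 0.4; differentially methylated regions (DMRs) are built from sites with
p < 1e-5, need >= 10 CpGs and an absolute mean difference >= 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from strainmeth.calls import CpGCountTable

logger = logging.getLogger(__name__)

WT_GT_KO, KO_GT_WT = "WT_gt_KO", "KO_gt_WT"

_PHI_MAX = 0.9


@dataclass
class TestParams:
    """All thresholds of the differential analysis, at their published defaults."""

    __test__ = False  # not a pytest class, despite the name

    tile_size: int = 1000
    tile_min_cov: int = 10
    tile_fdr: float = 0.01
    tile_diff: float = 0.4
    dmr_delta: float = 0.2
    dmr_p: float = 1e-5
    dmr_minCG: int = 10
    dmr_merge_gap: int = 100
    dmr_minlen: int = 50
    dmr_pct_sig: float = 0.5
    site_min_cov: int = 5  # 5 for WGBS summaries, 50 for capture DMR calling
    epi_fdr: float = 0.05
    smooth_span: int = 500

    def __post_init__(self) -> None:
        for name in ("tile_fdr", "tile_diff", "dmr_delta", "dmr_pct_sig", "epi_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("tile_size", "tile_min_cov", "dmr_minCG", "dmr_minlen", "site_min_cov"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _stack_group(tables: list[CpGCountTable]) -> pd.DataFrame:
    """Outer-join a group's tables into per-site replicate count columns."""
    frames = []
    for i, t in enumerate(tables):
        df = t.df.rename(columns={"meth": f"x{i}", "unmeth": f"u{i}"})
        frames.append(df.set_index(["chrom", "pos"]))
    joined = pd.concat(frames, axis=1).fillna(0)
    return joined


def _group_arrays(joined: pd.DataFrame, n_rep: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([joined[f"x{i}"].to_numpy(float) for i in range(n_rep)])
    n = x + np.stack([joined[f"u{i}"].to_numpy(float) for i in range(n_rep)])
    return x, n


def _mom_dispersion(x: np.ndarray, n: np.ndarray, p_pool: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-site method-of-moments dispersion across replicates plus a pooled
    genome-wide estimate; both on the beta-binomial correlation scale.

    Uses the unweighted replicate mean and the Bessel-corrected sample
    variance s^2 = sum_i (phat_i - pbar)^2 / (k - 1), whose expectation is
    mean_i Var(phat_i) = p(1-p) * (mean(1/n_i) + phi * mean((n_i-1)/n_i));
    solving for phi gives the estimator.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(n > 0, x / np.where(n > 0, n, 1), np.nan)
    k = np.sum(n > 0, axis=0)  # replicates informative at each site
    pbar = np.nanmean(phat, axis=0)
    with np.errstate(invalid="ignore"):
        s2 = np.nansum((phat - pbar) ** 2, axis=0) / np.maximum(k - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_n = np.where(n > 0, 1.0 / np.where(n > 0, n, 1), np.nan)
        frac = np.where(n > 0, (n - 1) / np.where(n > 0, n, 1), np.nan)
    mean_inv = np.nanmean(inv_n, axis=0)
    mean_frac = np.nanmean(frac, axis=0)
    pq = p_pool * (1 - p_pool)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 / np.where(pq > 0, pq, np.nan) - mean_inv) / np.where(
            mean_frac > 0, mean_frac, np.nan
        )
    # pooled estimate: ratio of summed excess variance to summed capacity
    ok = (k >= 2) & (pq > 0) & (mean_frac > 0)
    num = np.nansum(np.where(ok, s2 - pq * mean_inv, 0.0))
    den = np.nansum(np.where(ok, pq * mean_frac, 0.0))
    phi_global = float(np.clip(num / den, 0.0, _PHI_MAX)) if den > 0 else 0.0
    phi_site = np.clip(np.nan_to_num(raw, nan=phi_global), 0.0, _PHI_MAX)
    phi_site = np.where(ok, phi_site, phi_global)
    return phi_site, phi_global


def _local_dispersion(
    chroms: np.ndarray,
    pos: np.ndarray,
    x: np.ndarray,
    n: np.ndarray,
    span: int,
) -> tuple[np.ndarray, float]:
    """Single-replicate dispersion from neighbouring sites within +/- span/2.

    Treats nearby sites as pseudo-replicates of a locally constant level;
    with span 0 no local information exists and the dispersion is 0.
    """
    x1, n1 = x[0], n[0]
    m = len(pos)
    if span <= 0 or m == 0:
        return np.zeros(m), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(n1 > 0, x1 / np.where(n1 > 0, n1, 1), 0.0)
        inv_n = np.where(n1 > 0, 1.0 / np.where(n1 > 0, n1, 1), 0.0)
        frac = np.where(n1 > 0, (n1 - 1) / np.where(n1 > 0, n1, 1), 0.0)
    covered = (n1 > 0).astype(float)
    phi = np.zeros(m)
    raws = []
    half = span / 2
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        cpos = pos[sel]
        cum = lambda a: np.concatenate([[0.0], np.cumsum(a[sel])])
        cx, cn = cum(x1), cum(n1)
        cp, cp2 = cum(phat), cum(phat**2)
        cinv, cfrac, ccov = cum(inv_n), cum(frac), cum(covered)
        lo = np.searchsorted(cpos, cpos - half, side="left")
        hi = np.searchsorted(cpos, cpos + half, side="right")
        cnt = np.maximum(ccov[hi] - ccov[lo], 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pbar = np.where(cn[hi] - cn[lo] > 0, (cx[hi] - cx[lo]) / (cn[hi] - cn[lo]), 0.0)
            mean_sq = (cp2[hi] - cp2[lo]) / cnt - 2 * pbar * (cp[hi] - cp[lo]) / cnt + pbar**2
            mean_inv = (cinv[hi] - cinv[lo]) / cnt
            mean_frac = (cfrac[hi] - cfrac[lo]) / cnt
            pq = pbar * (1 - pbar)
            raw = (mean_sq / np.where(pq > 0, pq, np.nan) - mean_inv) / np.where(
                mean_frac > 0, mean_frac, np.nan
            )
        raws.append(raw)
        phi[sel] = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, _PHI_MAX)
    allraw = np.concatenate(raws) if raws else np.empty(0)
    finite = allraw[np.isfinite(allraw)]
    phi_global = float(np.clip(np.median(finite), 0.0, _PHI_MAX)) if finite.size else 0.0
    return phi, phi_global


def _pooled_var(n: np.ndarray, p: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Variance of the pooled proportion under the beta-binomial model."""
    contrib = n * p * (1 - p) * (1 + (n - 1) * np.where(n > 0, phi, 0.0))
    total = np.sum(n, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, np.sum(contrib, axis=0) / total**2, np.nan)


def dml_test(
    group_a: list[CpGCountTable],
    group_b: list[CpGCountTable],
    smooth_span: int = 500,
) -> pd.DataFrame:
    """Per-locus beta-binomial Wald test between two sample groups.

    Returns a DataFrame with columns ``chrom, pos, mu1, mu2, diff, phi1,
    phi2, stat, pval, qval``; ``diff = mu1 - mu2`` so that with group A =
    WT and group B = KO positive differences mean hypomethylation in KO.
    Only loci covered (pooled) in both groups are testable.
    """
    if not group_a or not group_b:
        raise ValueError("each group needs at least one sample")
    ja = _stack_group(group_a)
    jb = _stack_group(group_b)
    joined = ja.join(jb, how="inner", lsuffix="_a")
    if joined.empty:
        logger.warning("dml_test: no common sites between groups")
        return _empty_result()
    # column names collide when both groups have same replicate count; rebuild
    xa, na = _group_arrays(ja.loc[joined.index], len(group_a))
    xb, nb = _group_arrays(jb.loc[joined.index], len(group_b))
    keep = (na.sum(axis=0) > 0) & (nb.sum(axis=0) > 0)
    idx = joined.index[keep]
    xa, na, xb, nb = xa[:, keep], na[:, keep], xb[:, keep], nb[:, keep]
    if len(idx) == 0:
        logger.warning("dml_test: no co-covered sites between groups")
        return _empty_result()
    chroms = idx.get_level_values("chrom").to_numpy()
    pos = idx.get_level_values("pos").to_numpy()
    mu1 = xa.sum(axis=0) / na.sum(axis=0)
    mu2 = xb.sum(axis=0) / nb.sum(axis=0)
    phi1 = _dispersion(chroms, pos, xa, na, mu1, smooth_span)
    phi2 = _dispersion(chroms, pos, xb, nb, mu2, smooth_span)
    var1 = _pooled_var(na, mu1, phi1)
    var2 = _pooled_var(nb, mu2, phi2)
    d = mu1 - mu2
    se = np.sqrt(var1 + var2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, d / np.where(se > 0, se, 1), np.where(d == 0, 0.0, np.inf * np.sign(d)))
    pvals = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "mu1": mu1,
            "mu2": mu2,
            "diff": d,
            "phi1": phi1,
            "phi2": phi2,
            "stat": z,
            "pval": pvals,
            "qval": bh_fdr(pvals),
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def _dispersion(
    chroms: np.ndarray,
    pos: np.ndarray,
    x: np.ndarray,
    n: np.ndarray,
    p_pool: np.ndarray,
    span: int,
) -> np.ndarray:
    if x.shape[0] >= 2:
        phi_site, phi_global = _mom_dispersion(x, n, p_pool)
    else:
        phi_site, phi_global = _local_dispersion(chroms, pos, x, n, span)
    return 0.5 * phi_site + 0.5 * phi_global


def _empty_result() -> pd.DataFrame:
    cols = ["chrom", "pos", "mu1", "mu2", "diff", "phi1", "phi2", "stat", "pval", "qval"]
    return pd.DataFrame(columns=cols)


def tile_counts(table: CpGCountTable, tile_size: int = 1000) -> CpGCountTable:
    """Sum a sample's CpG counts into nonoverlapping [k*T, (k+1)*T) tiles.

    The resulting table uses the tile start as ``pos`` (a pseudo-locus),
    so tile-level testing reuses the site-level machinery unchanged.
    """
    df = table.df.copy()
    df["pos"] = (df["pos"] // tile_size) * tile_size
    tiled = df.groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "unmeth"]].sum()
    return CpGCountTable(tiled, table.sample)


def call_dmts(
    group_a: list[CpGCountTable],
    group_b: list[CpGCountTable],
    params: TestParams | None = None,
) -> pd.DataFrame:
    """Tile-level test and DMT call (group A hypermethylated, e.g. WT vs KO).

    A tile is eligible when every sample's pooled CpG coverage within it
    reaches ``tile_min_cov``; a DMT additionally needs q < ``tile_fdr`` and
    difference (A - B) > ``tile_diff``.  Returns the tile-level records
    with ``eligible`` and ``dmt`` flags, with ``start``/``end`` columns.
    """
    params = params or TestParams()
    tiles_a = [tile_counts(t, params.tile_size) for t in group_a]
    tiles_b = [tile_counts(t, params.tile_size) for t in group_b]
    eligible_keys = None
    for t in tiles_a + tiles_b:
        covered = t.df[(t.df["meth"] + t.df["unmeth"]) >= params.tile_min_cov]
        keys = set(zip(covered["chrom"], covered["pos"]))
        eligible_keys = keys if eligible_keys is None else (eligible_keys & keys)
    eligible_keys = eligible_keys or set()
    res = dml_test(tiles_a, tiles_b, smooth_span=0)
    if res.empty:
        res["start"] = res["end"] = res["eligible"] = res["dmt"] = []
        return res
    res["eligible"] = [
        (c, p) in eligible_keys for c, p in zip(res["chrom"], res["pos"])
    ]
    # q-values recomputed over eligible tiles only (the tested universe)
    res.loc[:, "qval"] = np.nan
    mask = res["eligible"].to_numpy()
    res.loc[mask, "qval"] = bh_fdr(res.loc[mask, "pval"].to_numpy())
    res["dmt"] = (
        mask
        & (res["qval"] < params.tile_fdr)
        & (res["diff"] > params.tile_diff)
    )
    res["start"] = res["pos"]
    res["end"] = res["pos"] + params.tile_size
    return res


@dataclass
class Dmr:
    """A called differentially methylated region."""

    chrom: str
    start: int  # 0-based half-open, first CpG's C
    end: int  # past the last CpG's G
    n_cg: int
    mean_diff: float
    direction: str
    frac_significant: float
    min_pval: float = 1.0
    sites: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def call_dmrs(records: pd.DataFrame, params: TestParams | None = None) -> list[Dmr]:
    """Group significant sites into DMRs.

    Sites with p < ``dmr_p`` seed regions; consecutive seeds closer than
    ``dmr_merge_gap`` extend one region, and every tested site inside the
    final span counts toward nCG and the mean difference.  Candidates must
    satisfy minCG, minimum span, seed fraction and |mean diff| >= delta.
    """
    params = params or TestParams()
    if records.empty:
        return []
    for chrom, sub in records.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("call_dmrs requires records sorted by position")
    dmrs: list[Dmr] = []
    for chrom, sub in records.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        pval = sub["pval"].to_numpy()
        diff = sub["diff"].to_numpy()
        seeds = np.flatnonzero(pval < params.dmr_p)
        if seeds.size == 0:
            continue
        runs: list[tuple[int, int]] = []
        run_start = seeds[0]
        prev = seeds[0]
        for s in seeds[1:]:
            if pos[s] - pos[prev] <= params.dmr_merge_gap:
                prev = s
            else:
                runs.append((run_start, prev))
                run_start = prev = s
        runs.append((run_start, prev))
        for a, b in runs:
            in_span = (pos >= pos[a]) & (pos <= pos[b])
            n_cg = int(in_span.sum())
            n_seed = int(np.sum(pval[in_span] < params.dmr_p))
            mean_d = float(diff[in_span].mean())
            span = int(pos[b]) + 2 - int(pos[a])
            if n_cg < params.dmr_minCG or span < params.dmr_minlen:
                continue
            if n_seed / n_cg < params.dmr_pct_sig or abs(mean_d) < params.dmr_delta:
                continue
            dmrs.append(
                Dmr(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]) + 2,
                    n_cg=n_cg,
                    mean_diff=mean_d,
                    direction=WT_GT_KO if mean_d > 0 else KO_GT_WT,
                    frac_significant=n_seed / n_cg,
                    min_pval=float(pval[in_span].min()),
                    sites=[int(p) for p in pos[in_span]],
                )
            )
    return _merge_adjacent(dmrs, params.dmr_merge_gap)


def _merge_adjacent(dmrs: list[Dmr], gap: int) -> list[Dmr]:
    merged: list[Dmr] = []
    for dmr in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
        if (
            merged
            and merged[-1].chrom == dmr.chrom
            and merged[-1].direction == dmr.direction
            and dmr.start - merged[-1].end <= gap
        ):
            prev = merged[-1]
            all_sites = prev.sites + dmr.sites
            n = len(all_sites)
            w_prev, w_new = prev.n_cg / n, dmr.n_cg / n
            merged[-1] = Dmr(
                chrom=prev.chrom,
                start=prev.start,
                end=dmr.end,
                n_cg=n,
                mean_diff=prev.mean_diff * w_prev + dmr.mean_diff * w_new,
                direction=prev.direction,
                frac_significant=prev.frac_significant * w_prev
                + dmr.frac_significant * w_new,
                min_pval=min(prev.min_pval, dmr.min_pval),
                sites=all_sites,
            )
        else:
            merged.append(dmr)
    return merged


def methylation_categories(table: CpGCountTable) -> tuple[float, float, float]:
    """Fractions of sites hypermethylated (>0.8), intermediate [0.2, 0.8],
    and hypomethylated (<0.2); the table should be coverage-filtered first."""
    if len(table) == 0:
        raise ValueError("category fractions undefined for an empty table")
    lv = table.level.to_numpy()
    hyper = float(np.mean(lv > 0.8))
    hypo = float(np.mean(lv < 0.2))
    inter = float(np.mean((lv >= 0.2) & (lv <= 0.8)))
    return hyper, inter, hypo


def chromosome_log2fc(
    ko: CpGCountTable, wt: CpGCountTable, min_shared_sites: int = 100
) -> dict[str, float | None]:
    """Per-chromosome log2(mean KO level / mean WT level) over shared sites."""
    merged = ko.df.merge(wt.df, on=["chrom", "pos"], suffixes=("_ko", "_wt"))
    out: dict[str, float | None] = {}
    chrom_names = list(dict.fromkeys(list(ko.df["chrom"]) + list(wt.df["chrom"])))
    for chrom in chrom_names:
        sub = merged[merged["chrom"] == chrom]
        if len(sub) < min_shared_sites:
            logger.info("chromosome_log2fc: %s has %d shared sites (<%d); skipped",
                        chrom, len(sub), min_shared_sites)
            out[chrom] = None
            continue
        mean_ko = (sub["meth_ko"] / (sub["meth_ko"] + sub["unmeth_ko"])).mean()
        mean_wt = (sub["meth_wt"] / (sub["meth_wt"] + sub["unmeth_wt"])).mean()
        if mean_wt == 0:
            out[chrom] = None
            continue
        out[chrom] = float(np.log2(mean_ko / mean_wt))
    return out


def dmrs_to_bed(dmrs: list[Dmr], path) -> None:
    """BED output: 0-based half-open, name=direction, score=-10*log10(p) capped."""
    with open(path, "w") as handle:
        for d in dmrs:
            score = min(1000, int(round(-10 * np.log10(max(d.min_pval, 1e-100)))))
            handle.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t{score}\t.\n")


def dmts_to_bed(tiles: pd.DataFrame, path) -> None:
    sub = tiles[tiles["dmt"]]
    with open(path, "w") as handle:
        for row in sub.itertuples():
            score = min(1000, int(round(-10 * np.log10(max(row.pval, 1e-100)))))
            handle.write(f"{row.chrom}\t{row.start}\t{row.end}\tWT_gt_KO\t{score}\t.\n")
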