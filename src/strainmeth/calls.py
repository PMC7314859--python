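"""Per-CpG methylation extraction, aggregation and coverage-file I/O.

Calls are made only at reference CpG dinucleotides, from the strand the
fragment actually derives from: top-strand fragments report the C of the
CpG (C observed = methylated, T = unmethylated), bottom-strand fragments
report the G at the following position, mapped back to the C coordinate so
that the two strands of one CpG merge into a single site record.

Read ends are ignored during extraction (defaults: first 10 bases of
either mate, last 5 of either mate) to suppress end-repair and M-bias
artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from strainmeth.align import AlignedPair, is_top_strand
from strainmeth.genome import FormatError, ReferenceGenome, index_cpg_sites

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimWindows:
    """Read-end windows excluded from methylation calls (read coordinates)."""

    ignore_5prime_r1: int = 10
    ignore_5prime_r2: int = 10
    ignore_3prime_r1: int = 5
    ignore_3prime_r2: int = 5

    def for_mate(self, mate: int) -> tuple[int, int]:
        if mate == 1:
            return self.ignore_5prime_r1, self.ignore_3prime_r1
        return self.ignore_5prime_r2, self.ignore_3prime_r2


class MethylationCall(NamedTuple):
    chrom: str
    site: int  # plus-strand C of the CpG, 0-based
    methylated: bool
    strand: str  # '+' top-strand evidence, '-' bottom-strand evidence
    read_id: str
    frag_key: tuple  # (chrom, start, end, strand) of the source fragment


def shared_cpg_index(
    genome1: ReferenceGenome, genome2: ReferenceGenome
) -> dict[str, np.ndarray]:
    """CpG sites present in both genomes (callable sites).

    A SNP can create or destroy a CpG in one strain; such sites are not
    comparable between alleles and are excluded from calling.
    """
    idx1 = index_cpg_sites(genome1)
    idx2 = index_cpg_sites(genome2)
    out = {}
    for chrom, pos1 in idx1.items():
        if chrom in idx2:
            out[chrom] = np.intersect1d(pos1, idx2[chrom])
        else:
            out[chrom] = pos1
    return out


def call_methylation(
    pair: AlignedPair,
    cpg_index: dict[str, np.ndarray],
    trim: TrimWindows | None = None,
) -> list[MethylationCall]:
    """Extract CpG methylation calls from one aligned pair.

    ``cpg_index`` holds the callable sites per chromosome (typically the
    shared CpG index of the two strain genomes).  Mate-overlap positions
    are counted once (mate 1 wins).
    """
    if trim is None:
        trim = TrimWindows()
    sites = cpg_index.get(pair.chrom)
    if sites is None or len(sites) == 0:
        return []
    top = is_top_strand(pair.strand)
    frag_key = pair.fragment_key()
    calls: list[MethylationCall] = []
    seen: set[int] = set()
    for mate in pair.mates:
        ignore5, ignore3 = trim.for_mate(mate.mate)
        if ignore5 + ignore3 >= mate.length:
            logger.debug("trim windows cover whole mate for %s", pair.read_id)
            continue
        # evidence position: the C itself (top) or the G at site+1 (bottom)
        shift = 0 if top else 1
        lo = np.searchsorted(sites, mate.pos - shift, side="left")
        hi = np.searchsorted(sites, mate.end - shift, side="left")
        for site in sites[lo:hi]:
            site = int(site)
            if site in seen:
                continue
            offset = site + shift - mate.pos
            off5 = mate.offset_from_5prime(offset)
            if off5 < ignore5 or off5 >= mate.length - ignore3:
                continue
            base = mate.fwd_seq[offset]
            if top:
                meth = base == "C"
                unmeth = base == "T"
            else:
                meth = base == "G"
                unmeth = base == "A"
            if not (meth or unmeth):
                continue
            seen.add(site)
            calls.append(
                MethylationCall(
                    pair.chrom, site, meth, "+" if top else "-", pair.read_id, frag_key
                )
            )
    return calls


def strand_restrict(items: Iterable, mode: str = "both") -> Iterator:
    """Filter calls or aligned pairs to bottom-strand evidence only.

    ``original_bottom_only`` emulates capture libraries whose probes target
    the original top strand, leaving only OB/CTOB data usable.
    """
    if mode not in ("both", "original_bottom_only"):
        raise ValueError(f"unknown strand restriction mode {mode!r}")
    for item in items:
        if mode == "both":
            yield item
            continue
        strand = item.strand
        keep = strand == "-" if strand in "+-" else not is_top_strand(strand)
        if keep:
            yield item


class CpGCountTable:
    """Per-CpG-site methylated/unmethylated counts for one sample.

    Backed by a DataFrame with columns ``chrom, pos, meth, unmeth`` sorted
    by position; ``pos`` is the plus-strand C of the CpG (0-based).
    """

    def __init__(self, df: pd.DataFrame, sample: str = "sample"):
        required = {"chrom", "pos", "meth", "unmeth"}
        if not required.issubset(df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if len(df) and ((df["meth"] < 0).any() or (df["unmeth"] < 0).any()):
            raise ValueError("negative counts")
        self.df = (
            df[["chrom", "pos", "meth", "unmeth"]]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.sample = sample

    def __len__(self) -> int:
        return len(self.df)

    @property
    def coverage(self) -> pd.Series:
        return self.df["meth"] + self.df["unmeth"]

    @property
    def level(self) -> pd.Series:
        cov = self.coverage
        return self.df["meth"] / cov.where(cov > 0)

    def filter(self, min_cov: int) -> "CpGCountTable":
        if min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        keep = self.coverage >= min_cov
        return CpGCountTable(self.df[keep], self.sample)

    def for_chrom(self, chrom: str) -> "CpGCountTable":
        return CpGCountTable(self.df[self.df["chrom"] == chrom], self.sample)

    def total_calls(self) -> int:
        return int(self.coverage.sum())

    def add(self, other: "CpGCountTable", sample: str | None = None) -> "CpGCountTable":
        """Site-wise sum of two tables (pooling replicates or alleles)."""
        merged = (
            pd.concat([self.df, other.df])
            .groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "unmeth"]]
            .sum()
        )
        return CpGCountTable(merged, sample or self.sample)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CpGCountTable):
            return NotImplemented
        return self.df.equals(other.df)


def aggregate_counts(
    calls: Iterable[MethylationCall],
    dedup: bool = True,
    sample: str = "sample",
) -> CpGCountTable:
    """Tally calls into a per-site count table.

    With ``dedup`` on, fragments sharing an identical (chrom, start, end,
    strand) key contribute once: the first read id seen for a key wins and
    later reads with the same key are dropped (PCR-duplicate removal).
    """
    counts: dict[tuple[str, int], list[int]] = {}
    chosen: dict[tuple, str] = {}
    for call in calls:
        if dedup:
            owner = chosen.setdefault(call.frag_key, call.read_id)
            if owner != call.read_id:
                continue
        bucket = counts.setdefault((call.chrom, call.site), [0, 0])
        bucket[0 if call.methylated else 1] += 1
    rows = [
        (chrom, pos, c[0], c[1]) for (chrom, pos), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    return CpGCountTable(df, sample)


def filter_table(table: CpGCountTable, min_cov: int) -> CpGCountTable:
    """Keep sites at coverage >= ``min_cov`` (5 for display, 10 tiles, 50 capture)."""
    return table.filter(min_cov)


def write_coverage(table: CpGCountTable, path: str | Path) -> None:
    """Write the 6-column coverage format (1-based inclusive, % to one decimal)."""
    with open(path, "w") as handle:
        for row in table.df.itertuples():
            cov = row.meth + row.unmeth
            pct = 100.0 * row.meth / cov if cov else 0.0
            handle.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.1f}\t{row.meth}\t{row.unmeth}\n"
            )


def read_coverage(path: str | Path, sample: str | None = None) -> CpGCountTable:
    """Read a coverage file; counts are authoritative, % is recomputed."""
    path = Path(path)
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 6:
                    chrom, start, _end, pct_s, meth_s, unmeth_s = fields
                    pct = float(pct_s)
                elif len(fields) == 5:
                    chrom, start, _end, meth_s, unmeth_s = fields
                    pct = None
                else:
                    raise ValueError("expected 5 or 6 columns")
                pos = int(start) - 1
                meth, unmeth = int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if pct is not None and meth + unmeth > 0:
                true_pct = 100.0 * meth / (meth + unmeth)
                if abs(true_pct - pct) > 0.05:
                    logger.warning(
                        "%s:%d: %% column %.1f disagrees with counts (%.1f); counts win",
                        path, lineno, pct, true_pct,
                    )
            rows.append((chrom, pos, meth, unmeth))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    return CpGCountTable(df, sample or path.stem)


def extract_sample(
    pairs: Iterable[AlignedPair],
    cpg_index: dict[str, np.ndarray],
    trim: TrimWindows | None = None,
    dedup: bool = True,
    strand_mode: str = "both",
    sample: str = "sample",
) -> CpGCountTable:
    """Convenience: strand-restrict, extract and aggregate one sample."""
    def _calls() -> Iterator[MethylationCall]:
        for pair in strand_restrict(pairs, strand_mode):
            yield from call_methylation(pair, cpg_index, trim)

    return aggregate_counts(_calls(), dedup=dedup, sample=sample)
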