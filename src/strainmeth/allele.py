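"""Dual-genome concordance filtering and allelic assignment of read pairs.

A read pair enters allelic analysis only if it maps uniquely to the same
chromosome and identical positions in both strain genomes (guaranteed to
be coordinate-compatible because the genomes differ by substitutions
only).  Assignment then rests on SNP base observations, with two
bisulfite-specific exclusions: SNPs inside CpG dinucleotides (base
confounded with methylation) and SNPs whose allele pair is erased by
conversion on the read's strand ({C,T} on top-strand reads, {G,A} on
bottom-strand reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from strainmeth.align import AlignedPair, is_top_strand
from strainmeth.calls import TrimWindows
from strainmeth.genome import SnpTable

GENOME1, GENOME2 = "genome1", "genome2"
UNASSIGNED, CONFLICT, DISCORDANT = "unassigned", "conflict", "discordant"


@dataclass
class AllelicAssignment:
    """Verdict for one read pair plus a per-SNP vote log for auditing."""

    read_id: str
    verdict: str
    votes1: int = 0
    votes2: int = 0
    n_inspected: int = 0
    n_skipped_cpg: int = 0
    n_skipped_blocked: int = 0
    n_skipped_trimmed: int = 0
    n_skipped_neither: int = 0
    n_skipped_quality: int = 0
    vote_log: list[tuple[str, int, str, int]] = field(default_factory=list)
    # vote_log rows: (chrom, pos, observed base, allele voted: 1 or 2)


class SnpIndex:
    """Per-chromosome arrays over an annotated SnpTable for fast overlap lookup."""

    def __init__(self, snps: SnpTable):
        df = snps.records
        required = {"in_cpg", "informative_ot", "informative_ob"}
        if not required.issubset(df.columns):
            raise ValueError("SnpTable must be annotated with informativeness flags first")
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = {
                "pos": sub["pos"].to_numpy(),
                "allele1": sub["allele1"].to_numpy(),
                "allele2": sub["allele2"].to_numpy(),
                "in_cpg": sub["in_cpg"].to_numpy(dtype=bool),
                "informative_ot": sub["informative_ot"].to_numpy(dtype=bool),
                "informative_ob": sub["informative_ob"].to_numpy(dtype=bool),
            }

    def overlapping(self, chrom: str, start: int, end: int) -> dict[str, np.ndarray]:
        cols = self._by_chrom.get(chrom)
        if cols is None:
            return {"pos": np.empty(0, dtype=int)}
        lo = np.searchsorted(cols["pos"], start, side="left")
        hi = np.searchsorted(cols["pos"], end, side="left")
        return {k: v[lo:hi] for k, v in cols.items()}


def dual_map_concordance(
    aln_g1: AlignedPair | None, aln_g2: AlignedPair | None
) -> str:
    """``"keep"`` when both genomes agree on a unique placement, else discordant.

    Agreement means: both pairs mapped, unique, same chromosome name, same
    leftmost positions for both mates, and same fragment strand.
    """
    if aln_g1 is None or aln_g2 is None:
        return DISCORDANT
    if not all(m.unique for m in aln_g1.mates + aln_g2.mates):
        return DISCORDANT
    if aln_g1.chrom != aln_g2.chrom or aln_g1.strand != aln_g2.strand:
        return DISCORDANT
    if aln_g1.mate1.pos != aln_g2.mate1.pos:
        return DISCORDANT
    m2a, m2b = aln_g1.mate2, aln_g2.mate2
    if (m2a is None) != (m2b is None):
        return DISCORDANT
    if m2a is not None and m2a.pos != m2b.pos:
        return DISCORDANT
    return "keep"


def assign_allele(
    pair: AlignedPair,
    snp_index: SnpIndex,
    policy: str = "strict",
    majority_fraction: float = 2 / 3,
    trim: TrimWindows | None = None,
    min_base_quality: int = 20,
) -> AllelicAssignment:
    """Assign one concordant pair to genome1/genome2 via informative SNPs.

    Under ``strict`` policy any split vote is a conflict; under ``majority``
    the winning allele needs at least ``majority_fraction`` of >=2 votes.
    Mate-overlap positions are examined once, with read 1's base taken.
    """
    if pair.strand is None:
        raise ValueError(f"pair {pair.read_id} lacks an origin strand")
    if trim is None:
        trim = TrimWindows()
    top = is_top_strand(pair.strand)
    out = AllelicAssignment(pair.read_id, UNASSIGNED)
    seen: set[int] = set()
    for mate in pair.mates:  # mate1 first: wins overlap disputes
        cols = snp_index.overlapping(pair.chrom, mate.pos, mate.end)
        n = len(cols["pos"])
        if n == 0:
            continue
        for i in range(n):
            pos = int(cols["pos"][i])
            if pos in seen:
                continue
            seen.add(pos)
            out.n_inspected += 1
            if cols["in_cpg"][i]:
                out.n_skipped_cpg += 1
                continue
            informative = cols["informative_ot"][i] if top else cols["informative_ob"][i]
            if not informative:
                out.n_skipped_blocked += 1
                continue
            offset = pos - mate.pos
            off5 = mate.offset_from_5prime(offset)
            ignore5 = trim.ignore_5prime_r1 if mate.mate == 1 else trim.ignore_5prime_r2
            ignore3 = trim.ignore_3prime_r1 if mate.mate == 1 else trim.ignore_3prime_r2
            if off5 < ignore5 or off5 >= mate.length - ignore3:
                out.n_skipped_trimmed += 1
                continue
            if mate.fwd_qual is not None and ord(mate.fwd_qual[offset]) - 33 < min_base_quality:
                out.n_skipped_quality += 1
                continue
            base = mate.fwd_seq[offset]
            match1 = base in _expected_observations(cols["allele1"][i], top)
            match2 = base in _expected_observations(cols["allele2"][i], top)
            if match1 and not match2:
                out.votes1 += 1
                out.vote_log.append((pair.chrom, pos, base, 1))
            elif match2 and not match1:
                out.votes2 += 1
                out.vote_log.append((pair.chrom, pos, base, 2))
            else:
                # matches neither, or both (cannot happen for informative SNPs:
                # overlapping observation sets are exactly the blocked pairs)
                out.n_skipped_neither += 1
    out.verdict = _verdict(out.votes1, out.votes2, policy, majority_fraction)
    return out


def _expected_observations(allele: str, top: bool) -> str:
    """Bases a read may legitimately show for this allele on this strand.

    Bisulfite conversion means a C allele can read as T on top-strand reads
    and a G allele as A (in forward orientation) on bottom-strand reads;
    counting those converted observations as votes is what makes
    C-containing SNP alleles scorable at all.
    """
    if top and allele == "C":
        return "CT"
    if not top and allele == "G":
        return "GA"
    return allele


def _verdict(v1: int, v2: int, policy: str, frac: float) -> str:
    total = v1 + v2
    if total == 0:
        return UNASSIGNED
    if policy == "strict":
        if v1 and not v2:
            return GENOME1
        if v2 and not v1:
            return GENOME2
        return CONFLICT
    if policy == "majority":
        if total >= 2:
            if v1 / total >= frac:
                return GENOME1
            if v2 / total >= frac:
                return GENOME2
        return CONFLICT if total >= 2 else UNASSIGNED
    raise ValueError(f"unknown policy {policy!r}")


def split_pairs(
    pairs_g1: dict[str, AlignedPair | None],
    pairs_g2: dict[str, AlignedPair | None],
    snp_index: SnpIndex,
    policy: str = "strict",
    trim: TrimWindows | None = None,
) -> dict[str, AllelicAssignment]:
    """Concordance-filter and assign every read id present in either genome map."""
    out: dict[str, AllelicAssignment] = {}
    for read_id in set(pairs_g1) | set(pairs_g2):
        p1 = pairs_g1.get(read_id)
        p2 = pairs_g2.get(read_id)
        if dual_map_concordance(p1, p2) == DISCORDANT:
            out[read_id] = AllelicAssignment(read_id, DISCORDANT)
            continue
        out[read_id] = assign_allele(p1, snp_index, policy=policy, trim=trim)
    return out


def assignment_table(assignments: dict[str, AllelicAssignment]):
    """Summarize verdicts as a DataFrame (read id, verdict, votes)."""
    import pandas as pd

    rows = [
        (a.read_id, a.verdict, a.votes1, a.votes2, a.n_inspected)
        for a in assignments.values()
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "verdict", "votes1", "votes2", "n_inspected"]
    ).sort_values("read_id", ignore_index=True)
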