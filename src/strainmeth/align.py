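"""Bisulfite read alignment against a converted reference.

Internal aligner for toy genomes only (ungapped, substitution-only,
seed-and-extend on exact 20-mers over the C->T and G->A reduced-alphabet
genome views); real data should arrive as externally produced SAM, which
:func:`read_sam` ingests.

Strand bookkeeping follows the standard bisulfite nomenclature: a fragment
derives from the original top (OT) or original bottom (OB) genomic strand;
in a directional paired-end library read 1 sequences the original strand
and read 2 its complement (CTOT/CTOB).  Both mates of an OT pair carry
top-strand methylation information once re-oriented to genome-forward
coordinates, and likewise for OB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from strainmeth.genome import FormatError, ReferenceGenome

logger = logging.getLogger(__name__)

OT, OB, CTOT, CTOB = "OT", "OB", "CTOT", "CTOB"
TOP_STRANDS = frozenset({OT, CTOT})
BOTTOM_STRANDS = frozenset({OB, CTOB})

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")
_CT = bytes.maketrans(b"C", b"T")
_GA = bytes.maketrans(b"G", b"A")
# base -> 2-bit code; N -> 4 (never matches, poisons seed hashes)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: XG (genome conversion) x XR (read conversion) -> bisulfite strand
SAM_TAG_STRANDS = {
    ("CT", "CT"): OT,
    ("CT", "GA"): CTOT,
    ("GA", "CT"): OB,
    ("GA", "GA"): CTOB,
}
#: per-mate SAM tags written for each fragment strand
_PAIR_TAGS = {
    (OT, 1): ("CT", "CT"),
    (OT, 2): ("CT", "GA"),
    (OB, 1): ("GA", "CT"),
    (OB, 2): ("GA", "GA"),
}


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def is_top_strand(strand: str) -> bool:
    if strand in TOP_STRANDS:
        return True
    if strand in BOTTOM_STRANDS:
        return False
    raise ValueError(f"unknown bisulfite strand {strand!r}")


def fragment_strand(strand: str) -> str:
    """Collapse a per-read strand label to the fragment's original strand."""
    return OT if is_top_strand(strand) else OB


@dataclass
class AlignedRead:
    """One mate of an aligned pair, stored in genome-forward orientation.

    ``fwd_seq`` is the unconverted observed sequence re-oriented so that it
    compares base-for-base against the plus strand of the reference;
    ``five_prime_left`` records whether the sequencer's 5' end of this mate
    sits at the leftmost genome coordinate (needed for end trimming, which
    is defined in read coordinates).
    """

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost
    strand: str  # OT / OB / CTOT / CTOB (per-read label)
    fwd_seq: str
    mate: int  # 1 or 2
    five_prime_left: bool
    unique: bool = True
    mismatches: int = 0
    source: str = "internal"
    fwd_qual: str | None = None  # Phred+33, genome-forward orientation

    @property
    def length(self) -> int:
        return len(self.fwd_seq)

    @property
    def end(self) -> int:
        return self.pos + self.length

    def offset_from_5prime(self, genome_offset: int) -> int:
        """Distance of a base from this mate's sequencing start."""
        return genome_offset if self.five_prime_left else self.length - 1 - genome_offset


@dataclass
class AlignedPair:
    """A concordantly aligned read pair (mate2 may be absent for single-end)."""

    read_id: str
    chrom: str
    strand: str  # fragment strand: OT or OB
    mate1: AlignedRead
    mate2: AlignedRead | None

    @property
    def fragment_start(self) -> int:
        if self.mate2 is None:
            return self.mate1.pos
        return min(self.mate1.pos, self.mate2.pos)

    @property
    def fragment_end(self) -> int:
        if self.mate2 is None:
            return self.mate1.end
        return max(self.mate1.end, self.mate2.end)

    @property
    def mates(self) -> list[AlignedRead]:
        return [m for m in (self.mate1, self.mate2) if m is not None]

    def fragment_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.fragment_start, self.fragment_end, self.strand)


class _ChromIndex:
    """Exact k-mer index over one converted chromosome view."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k
        n = len(codes) - k + 1
        window = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
        powers = (np.uint64(5) ** np.arange(k, dtype=np.uint64))
        hashes = window @ powers
        # windows containing N get hash >= 5^k only by accident; recompute validity
        valid = np.all(window < 4, axis=1)
        self.order = np.argsort(hashes[valid], kind="stable")
        self.valid_pos = np.flatnonzero(valid)
        self.sorted_hashes = hashes[valid][self.order]
        self.powers = powers

    def seed_hits(self, seed_codes: np.ndarray) -> np.ndarray:
        if np.any(seed_codes >= 4):
            return np.empty(0, dtype=np.int64)
        h = seed_codes.astype(np.uint64) @ self.powers
        lo = np.searchsorted(self.sorted_hashes, h, side="left")
        hi = np.searchsorted(self.sorted_hashes, h, side="right")
        return self.valid_pos[self.order[lo:hi]]


class ConvertedIndex:
    """Three-letter bisulfite index: C->T and G->A views of every chromosome."""

    def __init__(self, genome: ReferenceGenome, k: int = 20):
        self.genome = genome
        self.k = k
        self.views: dict[str, dict[str, np.ndarray]] = {"CT": {}, "GA": {}}
        self.indexes: dict[str, dict[str, _ChromIndex]] = {"CT": {}, "GA": {}}
        for name, seq in genome.chromosomes:
            if len(seq) < k:
                logger.warning("chromosome %s shorter than k=%d; skipped from index", name, k)
                continue
            raw = seq.encode("ascii")
            for view, table in (("CT", _CT), ("GA", _GA)):
                codes = _CODE[np.frombuffer(raw.translate(table), dtype=np.uint8)]
                self.views[view][name] = codes
                self.indexes[view][name] = _ChromIndex(codes, k)

    def converted_view(self, chrom: str, view: str) -> str:
        """The reduced-alphabet sequence (mainly for tests/debugging)."""
        codes = self.views[view][chrom]
        lut = np.frombuffer(b"ACGTN", dtype="S1")
        return lut[codes].tobytes().decode("ascii")


def build_converted_index(genome: ReferenceGenome, k: int = 20) -> ConvertedIndex:
    return ConvertedIndex(genome, k=k)


_BEST_NONE = (np.iinfo(np.int32).max, -1)


def _align_oriented(
    oriented: str,
    view: str,
    index: ConvertedIndex,
    max_mismatches: int,
) -> tuple[int, str | None, int, int]:
    """Align one conversion-oriented mate; return (best_mm, chrom, pos, second_mm).

    ``oriented`` is the read already re-oriented to genome-forward and NOT yet
    reduced; reduction happens here so the same conversion is applied to read
    and genome.  Ungapped extension counts mismatches over the full length in
    the reduced alphabet.
    """
    table = _CT if view == "CT" else _GA
    codes = _CODE[np.frombuffer(oriented.encode("ascii").translate(table), dtype=np.uint8)]
    k = index.k
    L = len(codes)
    if L < k:
        return (_BEST_NONE[0], None, -1, _BEST_NONE[0])
    offsets = sorted({0, (L - k) // 2, L - k})
    best_mm, best_chrom, best_pos, second_mm = _BEST_NONE[0], None, -1, _BEST_NONE[0]
    for chrom, chrom_index in index.indexes[view].items():
        genome_codes = index.views[view][chrom]
        seen: set[int] = set()
        for off in offsets:
            for hit in chrom_index.seed_hits(codes[off : off + k]):
                start = int(hit) - off
                if start < 0 or start + L > len(genome_codes) or start in seen:
                    continue
                seen.add(start)
                mm = int(np.count_nonzero(genome_codes[start : start + L] != codes))
                if mm < best_mm:
                    second_mm = best_mm
                    best_mm, best_chrom, best_pos = mm, chrom, start
                elif mm < second_mm:
                    second_mm = mm
    if best_mm > max_mismatches:
        return (_BEST_NONE[0], None, -1, _BEST_NONE[0])
    return best_mm, best_chrom, best_pos, second_mm


def align_read_pair(
    read_id: str,
    seq1: str,
    seq2: str,
    index: ConvertedIndex,
    max_mismatches: int = 4,
    max_fragment: int = 1000,
) -> AlignedPair | None:
    """Map a directional bisulfite read pair; ``None`` means unmapped.

    Both strand hypotheses are tried.  Under OT, read 1 is the converted top
    strand read forward and read 2 its reverse complement further right;
    under OB the mirror image.  A hypothesis wins only with strictly fewer
    total mismatches than the alternative (unique-best), and each mate must
    itself be unique-best among its candidate loci.
    """
    results = {}
    for hypo in (OT, OB):
        if hypo == OT:
            o1, o2, view = seq1, revcomp(seq2), "CT"
        else:
            o1, o2, view = revcomp(seq1), seq2, "GA"
        mm1, chrom1, pos1, sec1 = _align_oriented(o1, view, index, max_mismatches)
        mm2, chrom2, pos2, sec2 = _align_oriented(o2, view, index, max_mismatches)
        if chrom1 is None or chrom2 is None or chrom1 != chrom2:
            continue
        # unique-best per mate: strictly better than second best
        if sec1 <= mm1 or sec2 <= mm2:
            continue
        left, right = (pos1, pos2) if hypo == OT else (pos2, pos1)
        if right < left:
            continue
        span = max(pos1 + len(o1), pos2 + len(o2)) - min(pos1, pos2)
        if span > max_fragment:
            continue
        results[hypo] = (mm1 + mm2, chrom1, pos1, pos2, o1, o2)
    if not results:
        return None
    if len(results) == 2 and results[OT][0] == results[OB][0]:
        return None  # ambiguous between strands
    hypo = min(results, key=lambda h: results[h][0])
    _, chrom, pos1, pos2, o1, o2 = results[hypo]
    m1 = AlignedRead(
        read_id, chrom, pos1, hypo, o1, mate=1,
        five_prime_left=(hypo == OT),
        mismatches=results[hypo][0],
    )
    m2 = AlignedRead(
        read_id, chrom, pos2, hypo, o2, mate=2,
        five_prime_left=(hypo == OB),
    )
    return AlignedPair(read_id, chrom, hypo, m1, m2)


def align_pairs(
    pairs: Iterable[tuple[str, str, str]],
    index: ConvertedIndex,
    max_mismatches: int = 4,
    max_fragment: int = 1000,
) -> Iterator[tuple[str, AlignedPair | None]]:
    """Align a stream of ``(read_id, seq1, seq2)`` triples."""
    for read_id, s1, s2 in pairs:
        yield read_id, align_read_pair(read_id, s1, s2, index, max_mismatches, max_fragment)


def write_sam(path: str | Path, genome: ReferenceGenome, pairs: Iterable[AlignedPair]) -> None:
    """Write internal alignments as minimal SAM with bisulfite XG/XR tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in genome.lengths().items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            for mate in pair.mates:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = pair.read_id
                rec.reference_name = mate.chrom
                rec.reference_start = mate.pos
                rec.mapping_quality = 42
                rec.cigarstring = f"{mate.length}M"
                rec.query_sequence = mate.fwd_seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * mate.length)
                flag = 0x1 | 0x2
                flag |= 0x40 if mate.mate == 1 else 0x80
                if not mate.five_prime_left:
                    flag |= 0x10
                else:
                    flag |= 0x20
                rec.flag = flag
                other = pair.mate2 if mate.mate == 1 else pair.mate1
                if other is not None:
                    rec.next_reference_name = other.chrom
                    rec.next_reference_start = other.pos
                xg, xr = _PAIR_TAGS[(pair.strand, mate.mate)]
                rec.set_tag("XG", xg)
                rec.set_tag("XR", xr)
                out.write(rec)


def read_sam(
    path: str | Path,
    genome: ReferenceGenome,
    min_mapq: int = 20,
) -> Iterator[AlignedPair]:
    """Ingest external SAM alignments, yielding concordant pairs.

    Bisulfite strand is taken from the XG/XR tag pair when present and
    otherwise inferred from FLAG orientation under the directional-protocol
    assumption (read 1 forward => OT).  Records with MAPQ below ``min_mapq``
    are dropped, as are records with gapped CIGARs (the downstream model is
    substitution-only).
    """
    path = Path(path)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        if not sam.header.get("SQ"):
            raise FormatError(f"{path}: SAM header missing @SQ lines")
        pending: dict[str, AlignedRead] = {}
        n_dropped_mapq = n_dropped_cigar = n_inferred = 0
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            if rec.reference_name not in genome:
                raise FormatError(
                    f"{path}: chromosome {rec.reference_name!r} absent from reference"
                )
            if rec.mapping_quality < min_mapq:
                n_dropped_mapq += 1
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                n_dropped_cigar += 1
                continue
            strand = _record_strand(rec)
            if strand is None:
                n_inferred += 1
                strand = _infer_strand_from_flag(rec)
            mate_no = 2 if rec.is_read2 else 1
            aread = AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start,
                strand=strand,
                fwd_seq=rec.query_sequence.upper(),
                mate=mate_no,
                five_prime_left=not rec.is_reverse,
                source="external",
            )
            if not rec.is_paired:
                yield AlignedPair(aread.read_id, aread.chrom, fragment_strand(strand), aread, None)
                continue
            key = rec.query_name
            if key in pending:
                other = pending.pop(key)
                m1, m2 = (aread, other) if mate_no == 1 else (other, aread)
                if m1.chrom == m2.chrom:
                    yield AlignedPair(key, m1.chrom, fragment_strand(m1.strand), m1, m2)
            else:
                pending[key] = aread
        if n_inferred:
            logger.warning("read_sam: inferred strand from FLAG for %d records", n_inferred)
        if n_dropped_mapq or n_dropped_cigar:
            logger.info(
                "read_sam: dropped %d records below MAPQ %d and %d gapped records",
                n_dropped_mapq, min_mapq, n_dropped_cigar,
            )


def _record_strand(rec: pysam.AlignedSegment) -> str | None:
    if rec.has_tag("XG") and rec.has_tag("XR"):
        return SAM_TAG_STRANDS.get((rec.get_tag("XG"), rec.get_tag("XR")))
    return None


def _infer_strand_from_flag(rec: pysam.AlignedSegment) -> str:
    # directional protocol: read1 forward -> OT, read1 reverse -> OB;
    # read2 orientation is the opposite of its mate's.
    if rec.is_paired and rec.is_read2:
        return OB if not rec.is_reverse else OT
    return OT if not rec.is_reverse else OB
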