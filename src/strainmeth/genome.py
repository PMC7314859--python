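"""Reference genomes, strain SNP tables, and the alternate-genome build.

The analysis runs against two sequence-identical-coordinate genomes: the
reference strain ("genome1", e.g. B6/mm10) and an alternate strain
("genome2", e.g. MSM/Ms) reconstructed by substituting biallelic SNP
alleles into genome1.  Indels are deliberately not supported, which keeps
the two genomes coordinate-compatible: a read maps to the same position in
both, and allelic origin is decided purely from SNP base observations.

Coordinates are 0-based half-open internally; file formats (VCF, the TSV
SNP format, coverage files) use their native 1-based conventions at the
boundary.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_ALPHABET = frozenset("ACGTN")
_BASES = frozenset("ACGT")

#: default name patterns used to class chromosomes when no explicit map is given
_CLASS_PATTERNS = (
    (re.compile(r"^(chr)?Y$", re.IGNORECASE), "Y"),
    (re.compile(r"^(chr)?(M|MT)$", re.IGNORECASE), "MT"),
    (re.compile(r"^(chr)?X$", re.IGNORECASE), "X"),
)


class FormatError(ValueError):
    """Raised for unparseable input files; carries the offending line number."""


class ValidationError(ValueError):
    """Raised when an input is parseable but inconsistent with the genome."""


def classify_chromosome(name: str) -> str:
    """Class a chromosome as autosome/X/Y/MT from its name."""
    for pattern, cls in _CLASS_PATTERNS:
        if pattern.match(name):
            return cls
    return "autosome"


@dataclass
class ReferenceGenome:
    """An ordered set of named chromosome sequences.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, sequence)`` pairs.  Sequences are upper-cased and
        must be restricted to the A/C/G/T/N alphabet.
    chrom_class
        Optional explicit ``name -> {autosome, X, Y, MT}`` map; names not
        present are classed from their name pattern (chrY/chrM conventions).
    """

    chromosomes: list[tuple[str, str]]
    chrom_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        normalized = []
        for name, seq in self.chromosomes:
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"chromosome {name!r} has empty sequence")
            if set(seq) - _VALID_ALPHABET:
                bad = sorted(set(seq) - _VALID_ALPHABET)
                raise ValidationError(f"chromosome {name!r} contains invalid characters {bad}")
            normalized.append((name, seq))
        self.chromosomes = normalized
        for name in names:
            self.chrom_class.setdefault(name, classify_chromosome(name))
        self._by_name = {name: seq for name, seq in self.chromosomes}

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in genome") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def length(self, name: str) -> int:
        return len(self.sequence(name))

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}


def read_fasta(path: str | Path, chrom_class: dict[str, str] | None = None) -> ReferenceGenome:
    """Load a (optionally gzipped) FASTA file into a :class:`ReferenceGenome`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(records, dict(chrom_class or {}))


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    """Write a genome as FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


_SNP_COLUMNS = ["chrom", "pos", "allele1", "allele2"]
_FLAG_COLUMNS = ["in_cpg", "informative_ot", "informative_ob"]


@dataclass
class SnpTable:
    """Sorted biallelic substitution SNPs linking genome1 and genome2.

    ``records`` is a DataFrame with columns ``chrom, pos (0-based),
    allele1, allele2`` plus, after :func:`annotate_snp_informativeness`,
    boolean flags ``in_cpg, informative_ot, informative_ob``.
    ``allele1`` always equals the genome1 base at ``pos``.
    """

    records: pd.DataFrame
    skipped: int = 0  # multi-allelic / indel records dropped at load time

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True)
        missing = [c for c in _SNP_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"SnpTable missing columns {missing}")
        if len(df) and (df["allele1"] == df["allele2"]).any():
            raise ValidationError("SNP with identical alleles")
        for col in ("allele1", "allele2"):
            if len(df) and not df[col].isin(list(_BASES)).all():
                raise ValidationError(f"non-ACGT base in column {col}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.records = df
        self._positions_by_chrom: dict[str, np.ndarray] = {
            chrom: sub["pos"].to_numpy() for chrom, sub in df.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted SNP positions on one chromosome (empty if none)."""
        return self._positions_by_chrom.get(chrom, np.empty(0, dtype=int))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        df = self.records
        return df[df["chrom"] == chrom]

    def swapped(self) -> "SnpTable":
        """The same table with allele1/allele2 exchanged (genome-label swap)."""
        df = self.records.copy()
        df[["allele1", "allele2"]] = df[["allele2", "allele1"]].to_numpy()
        return SnpTable(df, skipped=self.skipped)

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV (1-based positions, informativeness flags appended)."""
        out = self.records.copy()
        out["pos"] = out["pos"] + 1
        cols = _SNP_COLUMNS + [c for c in _FLAG_COLUMNS if c in out.columns]
        out[cols].to_csv(path, sep="\t", index=False)


def _validate_snp_against_genome(
    chrom: str, pos: int, ref: str, genome: ReferenceGenome, lineno: int
) -> None:
    if chrom not in genome:
        raise ValidationError(f"line {lineno}: chromosome {chrom!r} absent from genome")
    if not (0 <= pos < genome.length(chrom)):
        raise ValidationError(f"line {lineno}: position {pos} outside {chrom}")
    base = genome.sequence(chrom)[pos]
    if base != ref:
        raise ValidationError(
            f"line {lineno}: ref allele {ref!r} does not match genome base {base!r} at {chrom}:{pos + 1}"
        )


def _iter_snp_lines(path: Path) -> Iterator[tuple[int, str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            yield lineno, line.rstrip("\n")


def load_snp_table(path: str | Path, genome: ReferenceGenome) -> SnpTable:
    """Load substitution SNPs from VCF or headerless 4-column TSV.

    TSV rows are ``chrom<TAB>pos1based<TAB>ref<TAB>alt``.  VCF records with
    non-single-base REF or ALT (indels, multi-allelic sites) are skipped and
    counted, matching a substitutions-only analysis.  Records whose REF base
    does not match genome1 raise :class:`ValidationError`.
    """
    path = Path(path)
    rows: list[tuple[str, int, str, str]] = []
    skipped = 0
    for lineno, line in _iter_snp_lines(path):
        if not line or line.startswith("#"):
            continue
        if line.startswith("chrom\tpos"):  # header row of an exported table
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: expected >=4 tab-separated fields")
        if len(fields) >= 5 and not (fields[2] in _BASES and fields[3] in _BASES):
            # VCF body: CHROM POS ID REF ALT ...
            chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        else:
            # TSV: chrom pos ref alt [flags...]
            chrom, pos_s, ref, alt = fields[0], fields[1], fields[2], fields[3]
        try:
            pos = int(pos_s) - 1
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer position {pos_s!r}") from None
        ref = ref.upper()
        alt = alt.upper()
        if len(ref) != 1 or len(alt) != 1 or "," in alt or ref not in _BASES or alt not in _BASES:
            skipped += 1
            continue
        if ref == alt:
            skipped += 1
            continue
        _validate_snp_against_genome(chrom, pos, ref, genome, lineno)
        rows.append((chrom, pos, ref, alt))
    if skipped:
        logger.info("load_snp_table: skipped %d non-substitution/multi-allelic records", skipped)
    df = pd.DataFrame(rows, columns=_SNP_COLUMNS)
    return SnpTable(df, skipped=skipped)


def snp_table_from_records(
    records: Iterable[tuple[str, int, str, str]], genome: ReferenceGenome | None = None
) -> SnpTable:
    """Build a SnpTable from in-memory ``(chrom, pos0, allele1, allele2)`` tuples."""
    df = pd.DataFrame(list(records), columns=_SNP_COLUMNS)
    table = SnpTable(df)
    if genome is not None:
        for row in table.records.itertuples():
            _validate_snp_against_genome(row.chrom, row.pos, row.allele1, genome, -1)
    return table


def reconstruct_alternate_genome(genome1: ReferenceGenome, snps: SnpTable) -> ReferenceGenome:
    """Substitute allele2 at every SNP position to build the strain genome.

    Chromosomes classed Y or MT are dropped from the result: without SNP
    data for them the alternate build would be uninformative, and allelic
    assignment there is impossible anyway.
    """
    out: list[tuple[str, str]] = []
    for name, seq in genome1.chromosomes:
        if genome1.chrom_class.get(name) in ("Y", "MT"):
            continue
        sub = snps.for_chrom(name)
        if len(sub):
            arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
            pos = sub["pos"].to_numpy()
            ref = sub["allele1"].to_numpy(dtype="S1")
            if not np.array_equal(arr[pos], ref):
                raise ValidationError(f"SNP ref mismatch on {name}")
            arr[pos] = sub["allele2"].to_numpy(dtype="S1")
            seq = arr.tobytes().decode("ascii")
        out.append((name, seq))
    cls = {name: genome1.chrom_class[name] for name, _ in out}
    return ReferenceGenome(out, cls)


def index_cpg_sites(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    """0-based positions of the plus-strand C of every CpG, per chromosome."""
    index: dict[str, np.ndarray] = {}
    for name, seq in genome.chromosomes:
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        is_c = arr[:-1] == b"C"
        is_g = arr[1:] == b"G"
        index[name] = np.flatnonzero(is_c & is_g)
    return index


def _overlaps_cpg(pos: int, cpg_positions: np.ndarray) -> bool:
    """True when ``pos`` is either base of a CpG dinucleotide."""
    i = np.searchsorted(cpg_positions, pos - 1)
    for j in (i, i + 1):
        if j < len(cpg_positions) and cpg_positions[j] in (pos - 1, pos):
            return True
    return False


def annotate_snp_informativeness(
    snps: SnpTable, genome1: ReferenceGenome, genome2: ReferenceGenome
) -> SnpTable:
    """Flag each SNP for CpG overlap and per-strand usability.

    Bisulfite chemistry erases two allele contrasts: on reads derived from
    the original top strand (OT/CTOT) every C may read as T, so a {C,T} SNP
    cannot be scored there; on original-bottom-derived reads (OB/CTOB) the
    forward-strand view shows G possibly as A, blocking {G,A} SNPs.  SNPs
    overlapping a CpG dinucleotide in either genome are excluded outright,
    because the base there is confounded with methylation state.
    """
    cpg1 = index_cpg_sites(genome1)
    cpg2 = index_cpg_sites(genome2)
    df = snps.records.copy()
    in_cpg = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples()):
        pos1 = cpg1.get(row.chrom, np.empty(0, dtype=int))
        pos2 = cpg2.get(row.chrom, np.empty(0, dtype=int))
        in_cpg[i] = _overlaps_cpg(row.pos, pos1) or _overlaps_cpg(row.pos, pos2)
    pair = df.apply(lambda r: frozenset((r["allele1"], r["allele2"])), axis=1) if len(df) else pd.Series([], dtype=object)
    blocked_ot = pair.apply(lambda s: s == frozenset("CT")).to_numpy(dtype=bool) if len(df) else np.empty(0, bool)
    blocked_ob = pair.apply(lambda s: s == frozenset("GA")).to_numpy(dtype=bool) if len(df) else np.empty(0, bool)
    df["in_cpg"] = in_cpg
    df["informative_ot"] = ~in_cpg & ~blocked_ot
    df["informative_ob"] = ~in_cpg & ~blocked_ob
    return SnpTable(df, skipped=snps.skipped)
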