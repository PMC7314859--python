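"""Synthetic diploid genomes, genotype-dependent methylomes and bisulfite reads.

The generator emulates the study design this package reproduces: an F1-like
diploid with dense strain SNPs (~1 per 150 bp), CpG islands at promoters, a
Polycomb-target (PcG) gene subset, an X-like chromosome, and three
genotypes —

* ``WT``: high genome-wide methylation, unmethylated autosomal CGIs,
  intermediate X-linked CGIs (mosaic X inactivation), methylated
  repeat-like intervals;
* ``KO3A`` (Dnmt3a-null-like): hypomethylated PcG promoters and gene
  bodies, everything else as WT;
* ``KO3B`` (Dnmt3b-null-like): hypomethylated X-linked CGIs, X
  non-island sites and repeat-like intervals, autosomes otherwise as WT.

Effect sizes are synthetic choices for testability (KO deltas of ~0.4 on
the mean), not estimates from any dataset.  Reads are directional
paired-end with configurable conversion efficiency, error rate and
coverage; read names carry full truth labels (``id|allele|strand|chrom|
start|fraglen``).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from strainmeth.align import OB, OT, AlignedPair, AlignedRead, revcomp
from strainmeth.genome import (
    ReferenceGenome,
    SnpTable,
    index_cpg_sites,
    snp_table_from_records,
)
from strainmeth.features import GeneAnnotation

GENOTYPES = ("WT", "KO3A", "KO3B")

#: (feature class, genotype) -> Beta(alpha, beta) methylation-probability law.
#: Classes are matched in precedence order: cgi/x_cgi > pcg_tss > pcg_body >
#: repeat > background/x_background.
DEFAULT_METH_PROFILE: dict[tuple[str, str], tuple[float, float]] = {
    ("background", "WT"): (8, 2),
    ("background", "KO3A"): (8, 2),
    ("background", "KO3B"): (8, 2),
    ("x_background", "WT"): (8, 2),
    ("x_background", "KO3A"): (8, 2),
    ("x_background", "KO3B"): (8, 12),
    ("cgi", "WT"): (1, 19),
    ("cgi", "KO3A"): (1, 19),
    ("cgi", "KO3B"): (1, 19),
    ("x_cgi", "WT"): (9, 11),
    ("x_cgi", "KO3A"): (9, 11),
    ("x_cgi", "KO3B"): (1, 19),
    ("pcg_tss", "WT"): (10, 10),
    ("pcg_tss", "KO3A"): (2, 18),
    ("pcg_tss", "KO3B"): (10, 10),
    ("pcg_body", "WT"): (14, 6),
    ("pcg_body", "KO3A"): (6, 14),
    ("pcg_body", "KO3B"): (14, 6),
    ("repeat", "WT"): (8, 2),
    ("repeat", "KO3A"): (8, 2),
    ("repeat", "KO3B"): (8, 12),
}

_CLASS_PRECEDENCE = ("cgi", "x_cgi", "pcg_tss", "pcg_body", "repeat")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_autosomes: int = 2
    chrom_length: int = 300_000
    include_X: bool = True
    n_genes_per_chrom: int = 20
    gene_length_min: int = 3_000
    gene_length_max: int = 6_000
    pcg_fraction: float = 0.25
    cgi_at_promoter_prob: float = 0.7
    cgi_halfwidth: int = 300
    n_repeats_per_chrom: int = 8
    repeat_length: int = 1_000
    snp_density: float = 1 / 150
    snp_cpg_fraction: float = 0.02
    genotype: str = "WT"
    meth_profile: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METH_PROFILE)
    )
    promoter_halfwidth: int = 1_000
    coverage: float = 20.0
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    conversion_rate: float = 0.99
    failed_conversion_rate: float = 0.01
    seq_error_rate: float = 0.001
    duplicate_rate: float = 0.0
    pbat_like: bool = False
    allele_effect: tuple[str, float] | None = None  # (class, delta on allele 2)
    base_quality: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pcg_fraction", "cgi_at_promoter_prob", "snp_density", "snp_cpg_fraction",
            "conversion_rate", "failed_conversion_rate", "seq_error_rate", "duplicate_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability, got {v}")
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if self.fragment_mean < self.read_length:
            raise ConfigError("fragment_mean must be >= read_length")
        if self.genotype not in GENOTYPES:
            raise ConfigError(f"genotype must be one of {GENOTYPES}")


class FastqRead(NamedTuple):
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class Methylome:
    """Per-CpG-site, per-allele methylation probabilities."""

    df: pd.DataFrame  # chrom, pos, klass, prob1, prob2

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = {
                "pos": sub["pos"].to_numpy(),
                "prob1": sub["prob1"].to_numpy(),
                "prob2": sub["prob2"].to_numpy(),
            }

    def site_probs(self, chrom: str, allele: int) -> tuple[np.ndarray, np.ndarray]:
        cols = self._by_chrom.get(chrom)
        if cols is None:
            return np.empty(0, dtype=int), np.empty(0)
        return cols["pos"], cols[f"prob{allele}"]


@dataclass
class TruthSet:
    """Everything the simulator knows: per-read origin, per-site laws,
    per-site drawn states, and the planted differential regions."""

    reads: pd.DataFrame  # read_id, allele, strand, chrom, start, frag_len
    methylome: Methylome
    planted_regions: pd.DataFrame  # chrom, start, end, klass, direction, effect
    state_counts: pd.DataFrame  # chrom, pos, meth_drawn, total_drawn

    def read_truth(self) -> dict[str, tuple]:
        return {
            r.read_id: (r.allele, r.strand, r.chrom, r.start, r.frag_len)
            for r in self.reads.itertuples()
        }


def parse_read_name(name: str) -> tuple[str, int, str, str, int, int]:
    """Decode ``id|allele|strand|chrom|start|fraglen`` truth labels."""
    rid, allele, strand, chrom, start, flen = name.split("|")
    return rid, int(allele), strand, chrom, int(start), int(flen)


# ---------------------------------------------------------------------------
# genome construction


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    # GC ~ 0.42 background composition
    return rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"), size=length, p=[0.29, 0.21, 0.21, 0.29]
    )


def _cgi_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-enriched island sequence (observed/expected CpG well above 0.6)."""
    out = np.empty(length, dtype="S1")
    i = 0
    singles = np.frombuffer(b"ACGT", dtype="S1")
    while i < length:
        if i + 1 < length and rng.random() < 0.15:
            out[i], out[i + 1] = b"C", b"G"
            i += 2
        else:
            out[i] = rng.choice(singles, p=[0.2, 0.3, 0.3, 0.2])
            i += 1
    return out


def build_toy_genome(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, GeneAnnotation, SnpTable]:
    """Random diploid scaffold: genome1 plus gene/CGI/repeat annotation and SNPs.

    Deterministic under ``config.seed``.  Genome2 is obtained separately via
    :func:`strainmeth.genome.reconstruct_alternate_genome`.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    slot = L // max(config.n_genes_per_chrom, 1)
    margin = config.promoter_halfwidth + config.cgi_halfwidth
    if config.n_genes_per_chrom and slot < config.gene_length_max + 2 * margin:
        raise ConfigError(
            f"cannot pack {config.n_genes_per_chrom} genes of up to "
            f"{config.gene_length_max} bp into {L} bp"
        )
    names = [f"chr{i + 1}" for i in range(config.n_autosomes)]
    if config.include_X:
        names.append("chrX")
    chroms: list[tuple[str, str]] = []
    gene_rows, cgi_rows, rep_rows = [], [], []
    snp_records: list[tuple[str, int, str, str]] = []
    for name in names:
        seq = _random_background(rng, L)
        n_pcg = int(round(config.pcg_fraction * config.n_genes_per_chrom))
        pcg_slots = set(rng.choice(config.n_genes_per_chrom, size=n_pcg, replace=False)) if n_pcg else set()
        gene_bounds = []
        for k in range(config.n_genes_per_chrom):
            glen = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
            lo = k * slot + margin
            hi = (k + 1) * slot - margin - glen
            start = int(rng.integers(lo, max(hi, lo + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (start, start + glen) if strand == "+" else (start + glen, start)
            gid = f"{name}_g{k:03d}"
            gene_rows.append((gid, name, strand, tss, tes, k in pcg_slots))
            gene_bounds.append((start, start + glen))
            if rng.random() < config.cgi_at_promoter_prob:
                c_lo = tss - config.cgi_halfwidth
                c_hi = tss + config.cgi_halfwidth
                seq[c_lo:c_hi] = _cgi_sequence(rng, c_hi - c_lo)
                cgi_rows.append((name, c_lo, c_hi, f"cgi_{gid}"))
        # repeat-like intervals in intergenic space (labels only, no sequence realism)
        placed = 0
        attempts = 0
        while placed < config.n_repeats_per_chrom and attempts < 200:
            attempts += 1
            start = int(rng.integers(0, L - config.repeat_length))
            interval = (start, start + config.repeat_length)
            near_gene = any(
                interval[0] < gb[1] + margin and gb[0] - margin < interval[1]
                for gb in gene_bounds
            )
            near_repeat = any(
                interval[0] < r[2] and r[1] < interval[1]
                for r in rep_rows if r[0] == name
            )
            if near_gene or near_repeat:
                continue
            rep_rows.append((name, interval[0], interval[1], "repeat"))
            placed += 1
        chroms.append((name, seq.tobytes().decode("ascii")))
        # SNPs: density-driven background outside CpGs plus a forced CpG subset
        arr = np.frombuffer(chroms[-1][1].encode("ascii"), dtype="S1")
        is_c = np.zeros(L, dtype=bool)
        is_c[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")
        in_cpg = is_c.copy()
        in_cpg[1:] |= is_c[:-1]
        n_total = int(np.count_nonzero(rng.random(L) < config.snp_density))
        n_forced = int(round(config.snp_cpg_fraction * n_total))
        cpg_positions = np.flatnonzero(in_cpg)
        open_positions = np.flatnonzero(~in_cpg)
        forced = (
            rng.choice(cpg_positions, size=min(n_forced, len(cpg_positions)), replace=False)
            if n_forced
            else np.empty(0, dtype=int)
        )
        non_cpg = rng.choice(
            open_positions, size=min(n_total - len(forced), len(open_positions)), replace=False
        )
        for pos in np.unique(np.concatenate([non_cpg, forced])):
            ref = arr[pos].decode("ascii")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            snp_records.append((name, int(pos), ref, alt))
    genome1 = ReferenceGenome(chroms)
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "is_pcg"])
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "label"])
    reps = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "label"])
    annotation = GeneAnnotation(genes, cgis, reps, dict(genome1.chrom_class))
    snps = snp_table_from_records(snp_records)
    return genome1, annotation, snps


# ---------------------------------------------------------------------------
# methylome assignment


def _class_intervals(annotation: GeneAnnotation, config: SimulationConfig) -> dict[str, list]:
    """Intervals per feature class (x_* variants resolved per chromosome class)."""
    out: dict[str, list[tuple[str, int, int]]] = {k: [] for k in _CLASS_PRECEDENCE}
    for row in annotation.cgis.itertuples():
        klass = "x_cgi" if annotation.chrom_class.get(row.chrom) == "X" else "cgi"
        out[klass].append((row.chrom, row.start, row.end))
    hw = config.promoter_halfwidth
    for g in annotation.genes.itertuples():
        if not g.is_pcg:
            continue
        out["pcg_tss"].append((g.chrom, g.tss - hw, g.tss + hw))
        out["pcg_body"].append((g.chrom, min(g.tss, g.tes), max(g.tss, g.tes)))
    for row in annotation.repeats.itertuples():
        out["repeat"].append((row.chrom, row.start, row.end))
    return out


def classify_sites(
    cpg_index: dict[str, np.ndarray],
    annotation: GeneAnnotation,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Assign every CpG site its most specific feature class."""
    intervals = _class_intervals(annotation, config)
    rows = []
    for chrom, positions in cpg_index.items():
        klass = np.array(
            ["x_background" if annotation.chrom_class.get(chrom) == "X" else "background"]
            * len(positions), dtype=object,
        )
        assigned = np.zeros(len(positions), dtype=bool)
        for name in _CLASS_PRECEDENCE:
            for c, start, end in intervals[name]:
                if c != chrom:
                    continue
                hit = (positions >= start) & (positions < end) & ~assigned
                klass[hit] = name
                assigned |= hit
        rows.append(pd.DataFrame({"chrom": chrom, "pos": positions, "klass": klass}))
    return pd.concat(rows, ignore_index=True)


def assign_methylome(
    annotation: GeneAnnotation,
    genome1: ReferenceGenome,
    config: SimulationConfig,
    genome2: ReferenceGenome | None = None,
    genotype: str | None = None,
) -> tuple[Methylome, pd.DataFrame]:
    """Draw a per-site methylation probability from each site's class law.

    Returns the methylome and the planted-region table: every interval whose
    class law under this genotype differs from WT (the truth for
    differential-methylation recovery tests).  When ``genome2`` is given,
    CpG sites existing only in genome2 (SNP-created) are included under the
    background law so allele-2 fragments have defined probabilities.
    """
    genotype = genotype or config.genotype
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    cpg1 = index_cpg_sites(genome1)
    sites = classify_sites(cpg1, annotation, config)
    if genome2 is not None:
        cpg2 = index_cpg_sites(genome2)
        extra_rows = []
        for chrom, positions in cpg2.items():
            extra = np.setdiff1d(positions, cpg1.get(chrom, np.empty(0, dtype=int)))
            if len(extra):
                bg = "x_background" if annotation.chrom_class.get(chrom) == "X" else "background"
                extra_rows.append(pd.DataFrame({"chrom": chrom, "pos": extra, "klass": bg}))
        if extra_rows:
            sites = (
                pd.concat([sites] + extra_rows, ignore_index=True)
                .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
            )
    probs = np.empty(len(sites))
    for klass in sites["klass"].unique():
        key = (klass, genotype)
        if key not in config.meth_profile:
            raise ConfigError(f"meth_profile missing entry for {key}")
        a, b = config.meth_profile[key]
        mask = (sites["klass"] == klass).to_numpy()
        probs[mask] = rng.beta(a, b, size=int(mask.sum()))
    df = sites.copy()
    df["prob1"] = probs
    df["prob2"] = probs
    if config.allele_effect is not None:
        klass, delta = config.allele_effect
        mask = (df["klass"] == klass).to_numpy()
        df.loc[mask, "prob2"] = np.clip(df.loc[mask, "prob2"] - delta, 0.0, 1.0)
    planted = _planted_regions(annotation, config, genotype)
    return Methylome(df), planted


def _planted_regions(
    annotation: GeneAnnotation, config: SimulationConfig, genotype: str
) -> pd.DataFrame:
    intervals = _class_intervals(annotation, config)
    rows = []
    for klass in _CLASS_PRECEDENCE + ("background", "x_background"):
        wt = config.meth_profile.get((klass, "WT"))
        ko = config.meth_profile.get((klass, genotype))
        if wt is None or ko is None or wt == ko:
            continue
        mean_wt = wt[0] / sum(wt)
        mean_ko = ko[0] / sum(ko)
        if klass in ("background", "x_background"):
            chrom_names = [
                c for c, cls in annotation.chrom_class.items()
                if (cls == "X") == (klass == "x_background")
            ]
            ivals = [(c, 0, 10**12) for c in chrom_names]
        else:
            ivals = intervals[klass]
        for chrom, start, end in ivals:
            rows.append(
                (chrom, start, end, klass,
                 "WT_gt_KO" if mean_wt > mean_ko else "KO_gt_WT",
                 mean_wt - mean_ko)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "klass", "direction", "effect"])


# ---------------------------------------------------------------------------
# read simulation

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_read_pairs(
    genome1: ReferenceGenome,
    genome2: ReferenceGenome,
    methylome: Methylome,
    config: SimulationConfig,
    planted_regions: pd.DataFrame | None = None,
    replicate: int = 0,
) -> tuple[list[FastqRead], TruthSet]:
    """Directional paired-end bisulfite reads from both alleles.

    Fragments are drawn until the expected sequenced-base total reaches
    ``coverage`` per position; each fragment picks an allele (Bernoulli 0.5)
    and an original strand (OT/OB, 0.5 each), draws per-CpG methylation
    states from the site law, applies conversion chemistry and sequencing
    errors.  ``planted_regions`` (from :func:`assign_methylome`) is carried
    into the returned :class:`TruthSet` when supplied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, replicate]))
    rl = config.read_length
    qual = chr(config.base_quality + 33)
    reads: list[FastqRead] = []
    truth_rows = []
    state_counts: dict[tuple[str, int], list[int]] = {}
    genomes = {1: genome1, 2: genome2}
    cpg_by_allele = {1: index_cpg_sites(genome1), 2: index_cpg_sites(genome2)}
    ridx = 0
    for chrom, seq in genome1.chromosomes:
        if chrom not in genome2:
            continue
        L = len(seq)
        target = config.coverage * L
        covered = 0.0
        site_probs = {a: methylome.site_probs(chrom, a) for a in (1, 2)}
        chrom_arrays = {
            a: np.frombuffer(genomes[a].sequence(chrom).encode("ascii"), dtype="S1")
            for a in (1, 2)
        }
        while covered < target:
            flen = int(np.clip(round(rng.normal(config.fragment_mean, config.fragment_sd)), rl, L))
            start = int(rng.integers(0, L - flen + 1))
            allele = 1 if rng.random() < 0.5 else 2
            strand = OT if rng.random() < 0.5 else OB
            frag = chrom_arrays[allele][start : start + flen].copy()
            pos_arr, prob_arr = site_probs[allele]
            allele_sites = cpg_by_allele[allele][chrom]
            lo = np.searchsorted(allele_sites, start, side="left")
            hi = np.searchsorted(allele_sites, start + flen - 1, side="left")
            frag_sites = allele_sites[lo:hi]
            idx = np.searchsorted(pos_arr, frag_sites)
            if len(frag_sites) and (
                idx.max() >= len(pos_arr) or not np.array_equal(pos_arr[idx], frag_sites)
            ):
                raise ConfigError(
                    "methylome lacks probabilities for some allele-2 CpG sites; "
                    "build it with assign_methylome(..., genome2=genome2)"
                )
            probs = prob_arr[idx]
            meth_states = rng.random(len(frag_sites)) < probs
            for site, meth in zip(frag_sites, meth_states):
                bucket = state_counts.setdefault((chrom, int(site)), [0, 0])
                bucket[0] += int(meth)
                bucket[1] += 1
            converted = _convert_fragment(
                rng, frag, frag_sites - start, meth_states, strand, config
            )
            name = f"r{ridx}|{allele}|{strand}|{chrom}|{start}|{flen}"
            reads.append(_make_fastq(rng, name, converted, flen, rl, qual, config))
            truth_rows.append((f"r{ridx}", allele, strand, chrom, start, flen))
            ridx += 1
            if config.duplicate_rate and rng.random() < config.duplicate_rate:
                dup_name = f"r{ridx}|{allele}|{strand}|{chrom}|{start}|{flen}"
                reads.append(_make_fastq(rng, dup_name, converted, flen, rl, qual, config))
                truth_rows.append((f"r{ridx}", allele, strand, chrom, start, flen))
                ridx += 1
            covered += min(flen, 2 * rl)
    if planted_regions is None:
        planted_regions = pd.DataFrame(
            columns=["chrom", "start", "end", "klass", "direction", "effect"]
        )
    truth = TruthSet(
        reads=pd.DataFrame(
            truth_rows, columns=["read_id", "allele", "strand", "chrom", "start", "frag_len"]
        ),
        methylome=methylome,
        planted_regions=planted_regions,
        state_counts=pd.DataFrame(
            [(c, p, m, t) for (c, p), (m, t) in sorted(state_counts.items())],
            columns=["chrom", "pos", "meth_drawn", "total_drawn"],
        ),
    )
    return reads, truth


def _convert_fragment(
    rng: np.random.Generator,
    frag: np.ndarray,
    cpg_offsets: np.ndarray,
    meth_states: np.ndarray,
    strand: str,
    config: SimulationConfig,
) -> np.ndarray:
    """Apply bisulfite chemistry to the strand actually sequenced.

    Returns the converted fragment in genome-forward orientation: for OT
    the C->T conversions appear directly; for OB the bottom strand is
    converted, which in forward orientation shows G->A changes.
    """
    out = frag.copy()
    if strand == OT:
        targets = np.flatnonzero(out == b"C")
        meth_offsets = cpg_offsets[meth_states]
        replacement = b"T"
    else:
        # bottom-strand C sits opposite the top-strand G at CpG offset + 1
        targets = np.flatnonzero(out == b"G")
        meth_offsets = cpg_offsets[meth_states] + 1
        replacement = b"A"
    if len(targets) == 0:
        return out
    is_meth = np.isin(targets, meth_offsets)
    rates = np.where(is_meth, config.failed_conversion_rate, config.conversion_rate)
    flips = rng.random(len(targets)) < rates
    out[targets[flips]] = replacement
    return out


def _make_fastq(
    rng: np.random.Generator,
    name: str,
    converted: np.ndarray,
    flen: int,
    rl: int,
    qual_char: str,
    config: SimulationConfig,
) -> FastqRead:
    fwd = converted.tobytes().decode("ascii")
    strand = name.split("|")[2]
    if strand == OT:
        r1 = fwd[:rl]
        r2 = revcomp(fwd[flen - rl :])
    else:
        bot = revcomp(fwd)
        r1 = bot[:rl]
        r2 = revcomp(bot[flen - rl :])
    r1 = _apply_errors(rng, r1, config.seq_error_rate)
    r2 = _apply_errors(rng, r2, config.seq_error_rate)
    return FastqRead(name, r1, qual_char * len(r1), r2, qual_char * len(r2))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in _BASE_BYTES if b != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode("ascii")


def write_fastq(reads: Iterable[FastqRead], path1: str | Path, path2: str | Path) -> None:
    """Write the pair as gzipped Phred+33 FASTQ files."""
    with gzip.open(path1, "wt") as h1, gzip.open(path2, "wt") as h2:
        for r in reads:
            h1.write(f"@{r.name}/1\n{r.seq1}\n+\n{r.qual1}\n")
            h2.write(f"@{r.name}/2\n{r.seq2}\n+\n{r.qual2}\n")


def alignments_from_truth(
    reads: list[FastqRead], read_length: int | None = None
) -> dict[str, AlignedPair]:
    """Perfect alignments reconstructed from truth labels (aligner bypass).

    Useful for testing extraction and statistics at scales where running
    the toy aligner would dominate runtime.
    """
    out: dict[str, AlignedPair] = {}
    for r in reads:
        rid, allele, strand, chrom, start, flen = parse_read_name(r.name)
        rl = read_length or len(r.seq1)
        if strand == OT:
            m1 = AlignedRead(r.name, chrom, start, strand, r.seq1, 1, True, fwd_qual=r.qual1)
            m2 = AlignedRead(
                r.name, chrom, start + flen - rl, strand, revcomp(r.seq2), 2, False,
                fwd_qual=r.qual2[::-1],
            )
        else:
            m1 = AlignedRead(
                r.name, chrom, start + flen - rl, strand, revcomp(r.seq1), 1, False,
                fwd_qual=r.qual1[::-1],
            )
            m2 = AlignedRead(r.name, chrom, start, strand, r.seq2, 2, True, fwd_qual=r.qual2)
        out[r.name] = AlignedPair(r.name, chrom, strand, m1, m2)
    return out


# ---------------------------------------------------------------------------
# truth evaluation


class IntegrityError(RuntimeError):
    pass


def allele_assignment_metrics(assignments: dict, truth: TruthSet) -> dict[str, float]:
    """Accuracy among assigned pairs plus the assignment rate."""
    truth_alleles = dict(zip(truth.reads["read_id"], truth.reads["allele"]))
    n_assigned = n_correct = n_total = 0
    for read_id, a in assignments.items():
        rid = read_id.split("|")[0]
        if rid not in truth_alleles:
            raise IntegrityError(f"read {read_id} absent from truth")
        n_total += 1
        verdict = a.verdict if hasattr(a, "verdict") else a
        if verdict in ("genome1", "genome2"):
            n_assigned += 1
            called = 1 if verdict == "genome1" else 2
            n_correct += int(called == truth_alleles[rid])
    return {
        "n_pairs": n_total,
        "assignment_rate": n_assigned / n_total if n_total else 0.0,
        "accuracy": n_correct / n_assigned if n_assigned else float("nan"),
    }


def methylation_mae(
    table, truth: TruthSet, min_cov: int = 1, against: str = "drawn"
) -> tuple[float, int]:
    """Mean absolute error of per-site level estimates against the truth.

    ``against="drawn"`` compares to the realized methylation fraction of
    the simulated molecules (the quantity the extractor actually observes,
    free of the binomial state-sampling floor); ``against="probability"``
    compares to the site's assigned Beta-law probability, allele-merged.
    """
    t = table.filter(min_cov)
    est = t.df.copy()
    est["level"] = est["meth"] / (est["meth"] + est["unmeth"])
    if against == "probability":
        truth_df = truth.methylome.df.copy()
        truth_df["truth_level"] = (truth_df["prob1"] + truth_df["prob2"]) / 2
    elif against == "drawn":
        truth_df = truth.state_counts.copy()
        truth_df = truth_df[truth_df["total_drawn"] > 0]
        truth_df["truth_level"] = truth_df["meth_drawn"] / truth_df["total_drawn"]
    else:
        raise ValueError(f"unknown truth mode {against!r}")
    merged = est.merge(
        truth_df[["chrom", "pos", "truth_level"]], on=["chrom", "pos"], how="inner"
    )
    if len(merged) < len(est):
        raise IntegrityError("estimated sites missing from truth methylome")
    mae = float(np.abs(merged["level"] - merged["truth_level"]).mean())
    return mae, len(merged)


def interval_jaccard(
    called: list[tuple[str, int, int]], truth: list[tuple[str, int, int]]
) -> float:
    """Base-pair Jaccard between two interval sets."""
    def to_masks(ivals):
        masks: dict[str, set[int]] = {}
        for chrom, start, end in ivals:
            masks.setdefault(chrom, set()).update(range(start, end))
        return masks

    a, b = to_masks(called), to_masks(truth)
    inter = sum(len(a.get(c, set()) & b.get(c, set())) for c in set(a) | set(b))
    union = sum(len(a.get(c, set()) | b.get(c, set())) for c in set(a) | set(b))
    return inter / union if union else 1.0


def region_recovery(
    called: list[tuple[str, int, int]],
    truth: list[tuple[str, int, int]],
) -> dict[str, float]:
    """Precision/recall by >=1 bp overlap plus base-pair Jaccard."""
    def overlaps(x, ivals):
        return any(x[0] == c and x[1] < e and s < x[2] for c, s, e in ivals)

    tp_called = sum(overlaps(c, truth) for c in called)
    recalled = sum(overlaps(t, called) for t in truth)
    return {
        "precision": tp_called / len(called) if called else float("nan"),
        "recall": recalled / len(truth) if truth else float("nan"),
        "jaccard": interval_jaccard(called, truth),
    }
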