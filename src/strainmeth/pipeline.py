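"""End-to-end orchestration of the allele-aware methylome analysis.

Chains simulation (or file input), dual-genome alignment, concordance
filtering, allelic assignment, methylation extraction and differential
testing.  Each stage is an ordinary function returning in-memory objects;
the CLI wraps these with file I/O and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from strainmeth import align as al
from strainmeth import allele as asplit
from strainmeth import calls as mc
from strainmeth import diff as dm
from strainmeth.features import GeneAnnotation
from strainmeth.genome import (
    ReferenceGenome,
    SnpTable,
    annotate_snp_informativeness,
    reconstruct_alternate_genome,
)
from strainmeth.simulate import (
    FastqRead,
    Methylome,
    SimulationConfig,
    TruthSet,
    alignments_from_truth,
    assign_methylome,
    build_toy_genome,
    simulate_read_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class SimSample:
    """One simulated sample with everything downstream stages need."""

    name: str
    config: SimulationConfig
    genome1: ReferenceGenome
    genome2: ReferenceGenome
    annotation: GeneAnnotation
    snps: SnpTable  # annotated with informativeness flags
    methylome: Methylome
    planted_regions: pd.DataFrame
    reads: list[FastqRead]
    truth: TruthSet


def simulate_sample(config: SimulationConfig, name: str | None = None) -> SimSample:
    """Build genome + methylome + reads for one genotype/seed."""
    genome1, annotation, snps = build_toy_genome(config)
    genome2 = reconstruct_alternate_genome(genome1, snps)
    snps = annotate_snp_informativeness(snps, genome1, genome2)
    methylome, planted = assign_methylome(
        annotation, genome1, config, genome2=genome2
    )
    reads, truth = simulate_read_pairs(genome1, genome2, methylome, config, planted)
    return SimSample(
        name=name or f"{config.genotype}_seed{config.seed}",
        config=config,
        genome1=genome1,
        genome2=genome2,
        annotation=annotation,
        snps=snps,
        methylome=methylome,
        planted_regions=planted,
        reads=reads,
        truth=truth,
    )


def simulate_replicate(sim: SimSample, replicate: int, name: str | None = None) -> SimSample:
    """A technical/biological replicate: same genome and methylome, fresh reads."""
    from dataclasses import replace

    reads, truth = simulate_read_pairs(
        sim.genome1, sim.genome2, sim.methylome, sim.config,
        sim.planted_regions, replicate=replicate,
    )
    return replace(sim, name=name or f"{sim.name}_rep{replicate}", reads=reads, truth=truth)


@dataclass
class SampleResult:
    """Alignment, assignment and count tables for one sample."""

    name: str
    assignments: dict[str, asplit.AllelicAssignment]
    table: mc.CpGCountTable  # allele-merged
    table_g1: mc.CpGCountTable
    table_g2: mc.CpGCountTable
    counters: dict[str, int] = field(default_factory=dict)


def process_sample(
    sim: SimSample,
    use_aligner: bool = True,
    trim: mc.TrimWindows | None = None,
    policy: str = "strict",
    max_mismatches: int = 4,
    dedup: bool = True,
    strand_mode: str = "both",
) -> SampleResult:
    """Align (or truth-place) reads, split alleles and extract methylation.

    ``use_aligner=False`` places reads at their truth loci, which is exact
    for simulated data and much faster; the aligner path exercises the full
    dual-genome mapping and concordance contract.
    """
    trim = trim or mc.TrimWindows()
    if use_aligner:
        idx1 = al.build_converted_index(sim.genome1)
        idx2 = al.build_converted_index(sim.genome2)
        pairs_g1: dict[str, al.AlignedPair | None] = {}
        pairs_g2: dict[str, al.AlignedPair | None] = {}
        for r in sim.reads:
            pairs_g1[r.name] = al.align_read_pair(r.name, r.seq1, r.seq2, idx1, max_mismatches)
            pairs_g2[r.name] = al.align_read_pair(r.name, r.seq1, r.seq2, idx2, max_mismatches)
    else:
        pairs_g1 = dict(alignments_from_truth(sim.reads))
        pairs_g2 = {k: v for k, v in pairs_g1.items()}
    snp_index = asplit.SnpIndex(sim.snps)
    assignments = asplit.split_pairs(pairs_g1, pairs_g2, snp_index, policy=policy, trim=trim)
    cpg_index = mc.shared_cpg_index(sim.genome1, sim.genome2)
    concordant = [
        pairs_g1[rid]
        for rid, a in assignments.items()
        if a.verdict != asplit.DISCORDANT and pairs_g1.get(rid) is not None
    ]
    table = mc.extract_sample(
        concordant, cpg_index, trim, dedup=dedup, strand_mode=strand_mode, sample=sim.name
    )
    by_allele = {asplit.GENOME1: [], asplit.GENOME2: []}
    for rid, a in assignments.items():
        if a.verdict in by_allele and pairs_g1.get(rid) is not None:
            by_allele[a.verdict].append(pairs_g1[rid])
    table_g1 = mc.extract_sample(
        by_allele[asplit.GENOME1], cpg_index, trim, dedup=dedup,
        strand_mode=strand_mode, sample=f"{sim.name}.genome1",
    )
    table_g2 = mc.extract_sample(
        by_allele[asplit.GENOME2], cpg_index, trim, dedup=dedup,
        strand_mode=strand_mode, sample=f"{sim.name}.genome2",
    )
    counters = _count_verdicts(assignments, pairs_g1)
    return SampleResult(sim.name, assignments, table, table_g1, table_g2, counters)


def _count_verdicts(assignments, pairs_g1) -> dict[str, int]:
    counters = {
        "pairs": len(assignments),
        "mapped_g1": sum(1 for p in pairs_g1.values() if p is not None),
    }
    for verdict in (
        asplit.GENOME1, asplit.GENOME2, asplit.UNASSIGNED, asplit.CONFLICT, asplit.DISCORDANT
    ):
        counters[verdict] = sum(1 for a in assignments.values() if a.verdict == verdict)
    return counters


@dataclass
class DiffResult:
    tiles: pd.DataFrame
    site_records: pd.DataFrame
    dmrs: list[dm.Dmr]


def pooled_coverage_filter(
    tables: list[mc.CpGCountTable], min_cov: int
) -> list[mc.CpGCountTable]:
    """Restrict each table to sites whose coverage pooled over the group
    reaches ``min_cov`` (coverage thresholds act on pooled counts)."""
    pooled = tables[0]
    for t in tables[1:]:
        pooled = pooled.add(t)
    keep = pooled.df.loc[pooled.coverage >= min_cov, ["chrom", "pos"]]
    out = []
    for t in tables:
        merged = t.df.merge(keep, on=["chrom", "pos"], how="inner")
        out.append(mc.CpGCountTable(merged, t.sample))
    return out


def differential_analysis(
    wt_tables: list[mc.CpGCountTable],
    ko_tables: list[mc.CpGCountTable],
    params: dm.TestParams | None = None,
) -> DiffResult:
    """Tile-level DMT calling plus site-level testing and DMR construction."""
    params = params or dm.TestParams()
    tiles = dm.call_dmts(wt_tables, ko_tables, params)
    wt_f = pooled_coverage_filter(wt_tables, params.site_min_cov)
    ko_f = pooled_coverage_filter(ko_tables, params.site_min_cov)
    sites = dm.dml_test(wt_f, ko_f, smooth_span=params.smooth_span)
    dmrs = dm.call_dmrs(sites, params)
    return DiffResult(tiles, sites, dmrs)


def write_manifest(
    path: str | Path,
    stage: str,
    inputs: dict[str, str | Path],
    params: dict,
    seed: int | None = None,
) -> None:
    """Record stage provenance: input hashes, parameters, versions, seed."""
    from strainmeth import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()
        },
    }
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str | None:
    p = Path(path)
    if not p.exists():
        return None
    digest = hashlib.sha256()
    with open(p, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _jsonable(v):
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    return str(v)
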