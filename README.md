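# strainmeth

Allele-aware bisulfite methylome analysis for hybrid (F1-like) designs:
strain-genome reconstruction from substitution SNPs, dual-genome bisulfite
read mapping with a concordance filter, conversion-aware assignment of read
pairs to parental alleles, per-CpG methylation extraction with end
trimming, and two-group differential methylation at CpG sites, 1-kb tiles
(DMTs) and merged regions (DMRs), plus gene/CGI-level summaries.

It is written for epigenomics researchers analysing whole-genome or
target-captured bisulfite sequencing from crosses between two inbred
strains (e.g. a laboratory strain × a wild-derived strain), where dense
SNPs let individual sequenced fragments be traced to a parental haplotype —
if the C↔T ambiguity introduced by bisulfite conversion is handled
correctly. A fully synthetic data generator with per-read truth labels
makes every stage testable without any external download.

## The statistics at the core

**Allelic assignment.** A read pair is kept only if it maps uniquely and
identically in both strain genomes (substitution-only genomes are
coordinate-compatible). SNPs inside CpG dinucleotides of either genome are
excluded; on reads from the original top strand a {C,T} SNP is unscorable
(conversion collapses the alleles), as is {G,A} on bottom-strand reads.
A C allele may legitimately read C or T on the top strand (and G as G/A on
the bottom), so votes match observation *sets*; under the strict policy any
conflicting vote discards the pair.

**Differential methylation.** At each locus the two groups are compared
with a Wald test on pooled proportions under a beta-binomial model: for
replicates with coverages n_i and dispersion φ,

    Var(p̂) = Σ n_i p(1−p)(1 + (n_i−1)φ) / (Σ n_i)²,
    z = (p̂₁ − p̂₂) / √(V₁ + V₂),

with φ estimated per locus by method of moments across replicates (or from
a local window for single replicates) and shrunk toward a genome-wide
estimate; q-values are Benjamini–Hochberg. Defaults mirror the published
thresholds: DMT = eligible 1-kb tile (pooled coverage ≥10 per sample) with
q < 0.01 and difference > 0.4; DMR = run of sites with p < 1e-5, ≥10 CpGs,
|mean difference| ≥ 0.2 at ≥50× pooled coverage. See `docs/methods.md`.

## Worked example

Simulate a wild-type vs Dnmt3a-KO-like contrast (two 120-kb autosomes, 30×
coverage, 2 replicates per group), run the full pipeline including the
internal bisulfite aligner, and identify the genes that lose methylation:

```python
from dataclasses import replace
from strainmeth import pipeline as pl
from strainmeth.diff import TestParams
from strainmeth.features import identify_target_genes
from strainmeth.simulate import SimulationConfig, allele_assignment_metrics

base = SimulationConfig(n_autosomes=2, chrom_length=120_000, include_X=False,
                        n_genes_per_chrom=8, pcg_fraction=0.25, coverage=30, seed=7)
wt = pl.simulate_sample(replace(base, genotype="WT"), name="WT")
ko = pl.simulate_sample(replace(base, genotype="KO3A"), name="KO3A")
wt_res = pl.process_sample(wt, use_aligner=True)
ko_res = pl.process_sample(ko, use_aligner=True)

m = allele_assignment_metrics(wt_res.assignments, wt.truth)
print(f"assigned {m['assignment_rate']:.1%} of pairs, accuracy {m['accuracy']:.4f}")

result = pl.differential_analysis(
    [wt_res.table, pl.process_sample(pl.simulate_replicate(wt, 1), use_aligner=True).table],
    [ko_res.table, pl.process_sample(pl.simulate_replicate(ko, 1), use_aligner=True).table],
    TestParams(site_min_cov=50),
)
print(f"{int(result.tiles['dmt'].sum())} DMTs, {len(result.dmrs)} DMRs")
targets = identify_target_genes(result.dmrs, wt.annotation)
print("target genes:", targets)
print("planted PcG :", wt.annotation.pcg_gene_ids())
```

Output:

```
assigned 53.7% of pairs, accuracy 0.9998
5 DMTs, 5 DMRs
target genes: ['chr1_g000', 'chr2_g000', 'chr2_g003']
planted PcG : ['chr1_g000', 'chr1_g005', 'chr2_g000', 'chr2_g003']
```

Read: about half the pairs carry a usable informative SNP (the rest are
*unassigned*, never guessed), and assignments are >99.9% correct. The
differential stage flags 5 hypomethylated tiles and 5 regions, which
recover 3 of the 4 planted Polycomb-target genes at this small scale —
`chr1_g005`'s promoter island keeps it below the region thresholds on this
seed. The assignment rate ceiling (~0.5 at 1 SNP/150 bp) is the price of
strict conversion-aware and CpG-exclusion rules; see `docs/methods.md`.

## Command-line pipeline

The same stages are available as subcommands over files (FASTA, VCF/TSV
SNPs, gzipped FASTQ, SAM, 6-column coverage):

```bash
strainmeth simulate  --config toy.ini --out-dir sim/
strainmeth align     --genome sim/genome1.fa --fastq1 sim/reads_1.fastq.gz \
                     --fastq2 sim/reads_2.fastq.gz --out g1.sam
strainmeth split     --sam-g1 g1.sam --sam-g2 g2.sam --genome1 sim/genome1.fa \
                     --genome2 sim/genome2.fa --snps sim/snps.tsv --out assign.tsv
strainmeth extract   --sam g1.sam --genome1 sim/genome1.fa --genome2 sim/genome2.fa \
                     --sample wt --out wt.cov
strainmeth diff      --wt wt.cov --ko ko.cov --out-dir diff/
strainmeth run-all   --config toy.ini --out-dir run/
```

Each stage writes a JSON manifest (input hashes, parameters, seed) for
exact re-runs. The internal aligner is intended for toy genomes (≤ ~10 Mb);
real data should be aligned externally and ingested as SAM (`--mode
capture` applies original-bottom-strand restriction and the ≥50× site
filter).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch on simulated data — toy diploid
genome, WT and KO read sets (two replicates each) through the dual-genome
aligner, allelic splitting, extraction, tile/region differential calling
and target-gene identification — logging assignment accuracy, methylation
recovery error and call counts to stderr, and writes the results JSON to
`--out`.
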