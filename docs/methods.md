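# Methods

`strainmeth` implements an allele-aware bisulfite methylome analysis for an
F1-like hybrid design: two parental genomes differing only by substitution
SNPs, dual-genome read mapping, conversion-aware allelic assignment, per-CpG
methylation extraction, and two-group differential methylation at CpG sites,
1-kb tiles and merged regions. This note records the models, the defaults and
why, what the synthetic data does and does not emulate, and the numerical
choices.

## Dual-genome model

The alternate strain genome ("genome2") is built from the reference
("genome1") by substituting the alternate allele at every biallelic SNP.
Indels are excluded by design, which keeps the two genomes
coordinate-compatible: a correctly mapped read occupies the same (chrom, pos)
in both, so the dual-mapping concordance filter can demand *identical*
placement, and no liftover is ever needed. Chromosomes classed Y or MT are
dropped from genome2 (no SNP data → no allelic signal there).

## Conversion-aware SNP logic

Bisulfite chemistry converts unmethylated C to T on the strand actually
sequenced. Viewed in genome-forward orientation, reads from the original top
strand (OT/CTOT) may show C→T changes and reads from the original bottom
strand (OB/CTOB) show G→A changes. Two consequences drive allelic
assignment:

1. **Blocked pairs.** A {C,T} SNP is unscorable on top-strand reads and a
   {G,A} SNP on bottom-strand reads — the conversion collapses the two
   alleles. These SNPs are flagged per strand and never vote there.
2. **Expanded matching.** On a scorable SNP, a C allele legitimately reads
   as C *or* T on top-strand reads (depending on its methylation/conversion
   state), and a G allele as G or A on bottom-strand reads. Votes therefore
   match against these observation sets; the sets of the two alleles can
   only overlap for the blocked pairs, so no ambiguity arises. Without this
   rule roughly a third of C/G-containing votes would be discarded.

SNPs overlapping a CpG dinucleotide in *either* genome are excluded outright
(the observed base is confounded with methylation state, and a
genome2-created CpG would bias allele-2 calls). This strict both-genome test
costs assignment yield — with 1 SNP per 150 bp and 2×100 bp reads the
assignment rate is ≈0.50 rather than the ≈0.65 a genome1-only test would
give — but removes a genuine bias channel. Assignment accuracy among
assigned pairs is >99.9% at a 0.1% sequencing error rate.

Policy: `strict` (default) calls an allele only on unanimous votes; any
split vote is a conflict and the pair is excluded downstream. `majority`
(≥2/3 of ≥2 votes) trades purity for yield. Votes respect the methylation
trim windows and a Phred≥20 base-quality floor when qualities are present.

## Methylation extraction

Calls are made only at reference CpG sites present in both genomes, from the
fragment's strand of origin: the C itself for top-strand fragments, the G at
site+1 (mapped back to the C coordinate) for bottom-strand fragments. Both
strands of one CpG merge into a single site record. The first 10 bases and
last 5 bases of each mate are ignored (end-repair / M-bias guard); enlarging
these windows can only remove calls, never add them (a tested invariant).
Mate overlaps are counted once (mate 1 wins). Deduplication collapses
fragments with identical (chrom, start, end, strand); it is on by default
for WGBS-mode and off for capture-mode, where `original_bottom_only` strand
restriction is applied instead (capture probes target one strand). Levels
are raw proportions; no conversion-efficiency correction is applied.

## Differential methylation

At each locus (site or tile) the test is a Wald test on the difference of
pooled group proportions under a beta-binomial count model. For group g with
replicate counts (x_i, n_i), pooled level p̂ = Σx/Σn and

    Var(p̂) = Σ_i n_i p(1-p) (1 + (n_i − 1) φ_g) / (Σ_i n_i)²

with dispersion φ_g on the intraclass-correlation scale. z = (p̂₁ −
p̂₂)/√(V₁+V₂), two-sided normal p, Benjamini–Hochberg q-values. d = 0 with
zero variance gives z = 0, p = 1; zero variance with d ≠ 0 gives p = 0.

**Dispersion.** With ≥2 replicates, φ is estimated per locus by method of
moments: the Bessel-corrected sample variance of replicate proportions
around their *unweighted* mean has expectation p(1−p)(mean(1/n_i) +
φ·mean((n_i−1)/n_i)); solving gives φ̂, clipped to [0, 0.9]. (Deviations
around the coverage-weighted pooled mean would lose a factor ≈(k−1)/k and
collapse the estimator at k=2.) Each per-locus estimate is shrunk 50:50
toward a genome-wide pooled-ratio estimate (summed excess variance over
summed capacity), which is stable where the per-locus χ²-noise is not. With
a single replicate per group, φ is estimated from loci within ±span/2
(default span 500 bp) treated as pseudo-replicates of a locally constant
level, shrunk toward the genome-wide median of window estimates; span 0
disables smoothing and reduces the test to binomial. Calibration under a
null with φ=0.01, 30× coverage and n=2/group: fraction of p<0.05 is
0.047–0.051 across seeds.

**Tiles (DMTs).** The genome is partitioned into abutting [k·1000,
(k+1)·1000) tiles; per sample, counts are summed over CpG sites in the tile
and the tile is tested as a pseudo-locus. Eligibility requires pooled CpG
coverage ≥10 in every sample; q-values are computed over eligible tiles. A
DMT needs q < 0.01 and difference (group A − group B) > 0.4 — the
hypomethylated-in-B direction, with A conventionally the wild type.

**Regions (DMRs).** Sites with p < 1e-5 seed regions; consecutive seeds ≤100
bp apart extend a region and every tested site inside the span counts.
Candidates must have ≥10 CpGs, span ≥50 bp, ≥50% significant sites and
|mean d| ≥ 0.2; adjacent same-direction regions ≤100 bp apart merge.
Coverage thresholds (≥5× display, ≥10× tiles, ≥50× region calling) are
applied to counts pooled within each group.

**Feature summaries.** Promoter = TSS±1000 bp (strand-independent span),
gene body = TSS..TES; region means are unweighted means of per-site levels
over sites with ≥5× coverage, undefined below 3 qualifying sites. Target
genes are genes whose [TSS−1000, TES] span overlaps (≥1 bp) a
WT-hypermethylated DMR. Distribution comparisons (KS, Mann–Whitney,
Wilcoxon signed-rank) use exact null distributions at small n (n_A·n_B ≤
10⁴, or n ≤ 25 for Wilcoxon); an all-zero paired difference vector reports
p = 1 with a warning.

## Synthetic data

The generator emulates the study design, not the mouse genome: random
GC≈0.42 chromosomes (2 autosomes + an X by default, 300 kb each), 20
non-overlapping genes per chromosome, CpG-enriched islands (observed/expected
CpG > 0.6) planted at 70% of promoters, a 25% PcG-target gene subset, labeled
repeat-like intervals (labels only — no transposon sequence realism), and
substitution SNPs at 1/150 bp with 2% forced into CpGs to exercise the
exclusion rules.

Methylation probabilities are drawn per CpG site from Beta laws by feature
class (precedence CGI > PcG TSS > PcG body > repeat > background):

| class | WT | KO3A | KO3B |
|---|---|---|---|
| background (autosome) | Beta(8,2) ≈ 0.80 | — | — |
| background (X) | Beta(8,2) ≈ 0.80 | — | Beta(8,12) ≈ 0.40 |
| CGI (autosome) | Beta(1,19) ≈ 0.05 | — | — |
| CGI (X) | Beta(9,11) ≈ 0.45 | — | Beta(1,19) ≈ 0.05 |
| PcG TSS±1 kb | Beta(10,10) ≈ 0.50 | Beta(2,18) ≈ 0.10 | — |
| PcG gene body | Beta(14,6) ≈ 0.70 | Beta(6,14) ≈ 0.30 | — |
| repeat-like | Beta(8,2) ≈ 0.80 | — | Beta(8,12) ≈ 0.40 |

("—" = same as WT.) These are synthetic choices for testability — KO mean
deltas of ≈0.4 — not estimates from any dataset. KO3A emulates loss of de
novo methylation at Polycomb targets; KO3B emulates loss at X-linked CGIs,
X non-island sites and repeats (the X-inactivation/satellite substrate).

Reads are directional paired-end: fragments N(250, 50) bp (≥ read length),
allele and original strand each Bernoulli(0.5), per-fragment CpG states
Bernoulli(site probability), non-CpG cytosines always unmethylated,
unmethylated C→T at the conversion rate (default 0.99), methylated C→T at
the failed-conversion rate (default 0.01), uniform substitution errors
(default 0.001), constant Phred 40. "Coverage" is mean sequenced-base
depth: fragments are drawn until sequenced bases reach coverage × genome
length. Truth (allele, strand, chrom, start, fragment length) rides in read
names; the truth set also stores every drawn methylation state, the site
laws and the planted differential intervals.

What a green test does *not* establish: robustness to indels, repetitive
sequence, CHH/CHG contexts, quality-score structure, chimeric reads or
mapping bias on a real genome — the toy genomes are unique by construction
and the internal aligner is intended for ≤10 Mb; real data should enter as
externally aligned SAM.

## Numerical and edge-case choices

- Coordinates 0-based half-open internally; 1-based at VCF/SAM/coverage
  boundaries. Coverage files: counts are authoritative, the % column is
  recomputed on read with a warning on disagreement.
- Category bins: hyper > 0.8, hypo < 0.2, intermediate closed [0.2, 0.8].
- Unique-best mapping: best alignment must beat the second best by ≥1
  mismatch, per mate and across strand hypotheses; ties are unmapped.
  Default max mismatches 4 per 100 bp (tolerates SNPs plus failed
  conversion on the non-converted channel).
- Per-chromosome log2 fold change requires ≥100 shared sites and a nonzero
  denominator; otherwise the chromosome is reported missing.
- Dispersion clipped to [0, 0.9]; empty tables and zero-coverage loci are
  dropped with warnings rather than producing NaN statistics.
- Determinism: every stochastic step derives from a single integer seed via
  independent named seed sequences (genome, methylome, reads×replicate);
  identical configs are byte-identical, replicates share genome and
  methylome but draw fresh reads.

## Known limitations

- The internal aligner is ungapped and substitution-only; indel-bearing
  reads must be pre-aligned externally.
- The Wald test is slightly liberal at very low coverage (<10×) where the
  normal approximation thins out; the published-threshold workflows all
  operate above that.
- Capture-mode deduplication is off by default (capture libraries
  deduplicate poorly by position); this is an interpretation, not a stated
  rule of the original workflow.
- The assignment-rate ceiling (~0.5 at 1 SNP/150 bp) is a consequence of
  the strict both-genome CpG exclusion; a genome1-only exclusion would
  raise yield at the cost of allele-biased calls at SNP-created CpGs.
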