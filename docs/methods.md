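# Methods

## The model

The package analyses pooled whole-genome bisulfite sequencing of two embryo
cohorts from one honey-bee colony and bisulfite-PCR amplicon clones from
candidate regions.  The colony carries exactly three segregating alleles:
P1 (drone-derived, paternal history), and M2/M3 (the queen's two alleles).

**Read model.**  At a cytosine, each read independently derives from one
chromosome copy of one pooled embryo.  Fertilized embryos are
(P1 paternal, M2 maternal) or (P1, M3) with equal probability, so a read
samples P1 with weight 1/2 and each maternal allele with weight 1/4.
Thelytokous embryos carry the same pairs but both copies maternally
transmitted.  Central-fusion loss of heterozygosity (per-locus probability
`loh_rate`, default 0.05) collapses a worker's (P1, Mᵢ) pair to either copy
with equal probability; because either copy is kept with probability 1/2,
the *pooled* read-level allele mixture is exactly unchanged (1/2, 1/4, 1/4).
The count-table simulator therefore uses the analytic mixture weights,
while the clone simulator draws the LOH event explicitly per molecule.
LOH is modelled independently per locus (no linkage map) because no stage
of the analysis uses linkage.

**Methylation truth.**  Truth is assigned per CpG dyad, per allele, per
transmission sex, and is bimodal: dyads inside a methylated gene body
(fraction `frac_methylated_genes`, default 0.5 — about half of genes are
methylated in the honey bee) have level `high_meth_level` (default 0.8,
matching the high median frequencies of genuinely methylated sites);
everything else has `low_meth_level` (default 0).  Two perturbation regimes
can be overlaid per dyad: *imprinted* (add `imprint_delta` when the copy was
paternally transmitted — only possible in fertilized embryos, which is the
design's key lever) and *cis_asm* (add a fixed per-allele offset, default
(0.45, 0, 0.25), regardless of transmission; this reproduces
high/low/intermediate per-allele profiles like those seen at validated ASM
loci).  All probabilities are clipped to [0, 1].

**Observation model.**  Coverage is Poisson(`mean_coverage`, default 10,
matching ~8.6–10.1× genome coverage).  A read at a site with truth `f` is
observed non-converted with probability
`f·(1−overconversion_rate) + (1−f)·(1−conversion_rate)`; defaults
`conversion_rate = 0.997` (the spike-in estimate scale) and
`overconversion_rate = 0.005` (protection failure; small, unquantified in
real data).  The spike-in control is a lambda-like random sequence with
truth `f = 0` everywhere (default 10,000 cytosines).  SNPs occur per bp at
rate `snp_rate` (default 0.005) with a uniform alternate base and a random
segregating pattern over the three alleles; they both create and destroy
CpG sites, which the truth tables track per allele — reads from an allele
whose CpG was destroyed count as converted, the same artefact that produces
apparent non-CpG methylation in real alignments.

## What the simulator does not emulate

Read-level artefacts (alignment error, M-bias, PCR duplicates, chimeric
amplicons), sequence composition beyond i.i.d. bases with a GC fraction,
linkage between loci, and more than one colony/chromosome.  Passing tests
therefore demonstrate correctness of the statistics and the inheritance
logic under the stated generative model, not robustness to mapping
artefacts in real libraries.

## Analysis conventions

* Cytosines are counted **per strand**; symmetric CpG partners are separate
  sites (merging would halve CG totals and break comparability with
  strand-resolved count tables).
* Binomial calling: one-sided upper tail, `p₀ = 1 − conversion rate`,
  computed by exact log-space summation (no normal approximation; stable at
  arbitrary depth).  BH correction is applied across all sites with ≥ 1
  read, per sample; `alpha = 0.05`.  Genome-wide summaries use the coverage
  window [2, 30] (both bounds configurable).
* Differential methylation: two-sided Fisher's exact test per site (the
  appropriate exact test for two pooled samples without replicates),
  re-implemented in-package by hypergeometric enumeration with a 1e-7
  relative tie tolerance; raw `p ≤ 0.05` and ≥ 25-point difference, with an
  optional BH mode off by default since the thresholding convention for
  unreplicated pools uses raw p.  The difference is `a − b` (fertilized
  minus thelytokous when run through the pipeline).
* Chi-square tests carry no continuity correction; the directional-bias
  test is a 1-df goodness-of-fit against equal expectation.
* Gene context: exon beats intron when genes overlap; among equal
  categories the gene with the smaller start, then lexicographic id, is
  reported.  Intergenic sites are never gene-assigned.  The per-gene
  "region" is max − min + 1 over that gene's hypermethylated sites.
* Coordinates: 0-based half-open internally, 1-based inclusive in all I/O.

## Haplotyping and the verdict rule

Amplicons assay one strand (plus strand in the simulator).  After
conversion the observation sets are A→{A}, G→{G}, T→{T}, C→{C,T}; a SNP
distinguishes an allele pair only when their sets are disjoint, so C/T
pairs are confounded and G/A pairs are fully informative.  Clones align to
the region reference with match = +1, mismatch = −1, gap open/extend =
−4/−1, free end gaps, and reference-C ~ read-T scored as a match; an exact
ungapped comparison is tried first.  Clones below 70 % wildcard identity,
or ambiguous at assignment (`min_informative = 1` covered informative SNPs
required), are excluded and reported in a QC block — degraded loci then
fall back to `insufficient_data` rather than a forced call.

Per-allele overall percentages use the fixed possible-CpG-site denominator
(methylated calls / (possible sites × assigned clones)), even when an
allele's assayable set is smaller; per-site fractions use assayable clones
only; cross-mode and heterogeneity tests use pooled site-calls.  The
verdict rule (thresholds all configurable and echoed in the output):
with every allele×mode cell holding ≥ `min_calls` = 30 pooled calls,

* `cis_asm` — allele heterogeneity significant in *both* modes and no
  BH-adjusted cross-mode test below alpha;
* `parent_of_origin` — the paternal-history allele's adjusted cross-mode
  test below alpha and its |Δ%| larger than every maternal allele's;
* `mixed` — both signatures; `inconclusive` — neither;
* `insufficient_data` — any cell under `min_calls`.

The pooled-call denominator and this decision rule are this package's own
design choices for an otherwise informally described comparison; alpha and
`min_calls` defaults were fixed before any simulation was scored.  Note
that the rule is deliberately strict about cross-mode shifts: with very
large call counts per cell even small allele-level drifts between modes
become significant and push a haplotype-stable locus from `cis_asm` to
`inconclusive`; at the 30–200 calls/cell typical of 20-clone experiments
the rule behaves as intended.

## Problem sizes used in tests and acceptance runs

Chosen as desk-scale defaults that keep every property measurable: 1e4+ CpG
strand-sites (≈170 kb genome) for error control, 3e5 spike-in read
observations for conversion recovery, 20 replicate 100 kb colonies for the
direction-bias property, and 100 simulated 1.6 kb loci per regime (≈45 CpGs,
~16 SNPs, 20 clones/sample) for verdict accuracy.  The full pipeline on the
default 500 kb / 50-gene genome completes in seconds.

## Known limitations

Single colony, single chromosome, no replicate-aware differential testing
(the design has one pooled library per mode), no DMR/window smoothing, no
isoform-level annotation, and no modelling of why a validated amplicon
might show systematically lower methylation than the genome-wide library
for the same locus (unequal allele sampling at modest coverage is one
plausible cause; the package reports per-allele clone counts so users can
see it).
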