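"""Simulator for the Cape honey-bee (A. m. capensis) breeding design.

The design being emulated: a queen carrying two alleles (M2, M3) is
inseminated by a single drone (allele P1).  Her fertilized embryos carry the
paternally transmitted P1 plus one maternal allele.  After queen removal her
daughter workers lay diploid eggs by thelytokous parthenogenesis (central
fusion of two worker pronuclei), so thelytokous embryos carry (P1, M2) or
(P1, M3) with BOTH copies maternally transmitted, collapsing to a homozygous
pair at a locus with per-locus probability ``loh_rate`` (loss of
heterozygosity distal to a crossover).

Methylation truth is assigned per CpG dyad, per allele, per transmission sex:

* baseline — gene-body methylation: dyads inside a randomly chosen fraction
  of genes get a high level, everything else a low level;
* imprinted — ``imprint_delta`` is added when the copy was paternally
  transmitted (only possible in fertilized embryos, the design's key lever);
* cis_asm — a fixed per-allele offset is added regardless of transmission.

Observed bisulfite counts follow: coverage ~ Poisson(mean_coverage); each
read samples an allele copy (1/2 P1, 1/4 M2, 1/4 M3 — LOH collapse picks
either copy with equal odds so the pooled mixture is exactly unchanged);
a read is non-converted (reads C) with probability
f*(1-overconversion_rate) + (1-f)*(1-conversion_rate).  A fully
unmethylated lambda-like spike-in is generated alongside each sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedWorld",
    "Gene",
    "AmpliconCloneSet",
    "Clone",
    "ALLELES",
    "FERTILIZED",
    "THELYTOKOUS",
    "build_world",
    "simulate_count_table",
    "simulate_clones",
    "write_world",
    "write_clone_fasta",
    "ConfigError",
]

ALLELES = ("P1", "M2", "M3")
FERTILIZED = "fertilized"
THELYTOKOUS = "thelytokous"
MODES = (FERTILIZED, THELYTOKOUS)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulated colony, genome and assay.

    Defaults are the study conditions: conversion rate 0.997 (spike-in
    estimate scale), ~10x coverage, half of genes methylated with a high
    bimodal level of 0.8, a 500 kb desk-scale genome.
    """

    seed: int = 0
    genome_length: int = 500_000
    n_genes: int = 50
    exons_per_gene: Tuple[int, int] = (2, 6)
    gc_fraction: float = 0.35
    snp_rate: float = 0.005
    frac_methylated_genes: float = 0.5
    high_meth_level: float = 0.8
    low_meth_level: float = 0.0
    frac_imprinted_loci: float = 0.0
    imprint_delta: float = 0.5
    frac_cis_asm_loci: float = 0.0
    asm_allele_offsets: Tuple[float, float, float] = (0.45, 0.0, 0.25)
    loh_rate: float = 0.05
    conversion_rate: float = 0.997
    overconversion_rate: float = 0.005
    mean_coverage: float = 10.0
    n_control_sites: int = 10_000
    n_embryos_per_pool: int = 300
    chrom_name: str = "chrSim1"

    def validate(self) -> None:
        probs = {
            "gc_fraction": self.gc_fraction,
            "snp_rate": self.snp_rate,
            "frac_methylated_genes": self.frac_methylated_genes,
            "high_meth_level": self.high_meth_level,
            "low_meth_level": self.low_meth_level,
            "frac_imprinted_loci": self.frac_imprinted_loci,
            "frac_cis_asm_loci": self.frac_cis_asm_loci,
            "loh_rate": self.loh_rate,
            "conversion_rate": self.conversion_rate,
            "overconversion_rate": self.overconversion_rate,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if not (-1.0 <= self.imprint_delta <= 1.0):
            raise ConfigError("imprint_delta must lie in [-1,1]")
        if self.frac_imprinted_loci + self.frac_cis_asm_loci > 1.0:
            raise ConfigError("imprinted + cis-ASM locus fractions exceed 1")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if self.n_genes < 0 or self.n_control_sites < 0:
            raise ConfigError("counts must be non-negative")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("exons_per_gene must be a range with 1 <= lo <= hi")
        if self.n_genes > 0:
            slot = self.genome_length // self.n_genes
            if slot < hi * 6 + 10:
                raise ConfigError(
                    f"{self.n_genes} genes with up to {hi} exons cannot fit in "
                    f"{self.genome_length} bp"
                )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: Tuple[Tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons[:-1], self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass
class SimulatedWorld:
    """Genome, three allele haplotypes, gene models and methylation truth."""

    config: SimulationConfig
    reference: str
    snps: pd.DataFrame  # pos(0-based), ref, P1, M2, M3
    allele_seqs: Dict[str, str]
    genes: List[Gene]
    methylated_genes: frozenset
    # union of CpG dyad start positions over reference + all alleles (0-based)
    dyad_pos: np.ndarray
    dyad_regime: np.ndarray  # 'baseline' | 'imprinted' | 'cis_asm'
    dyad_baseline: np.ndarray
    # per allele: boolean mask over dyad_pos (dyad intact on that allele)
    dyad_in_allele: Dict[str, np.ndarray]
    # per allele: truth f under maternal / paternal transmission, 0 where absent
    f_maternal: Dict[str, np.ndarray]
    f_paternal: Dict[str, np.ndarray]

    def cg_registry(self, allele: str) -> np.ndarray:
        """0-based CpG dyad start positions present on the given allele."""
        return self.dyad_pos[self.dyad_in_allele[allele]]

    def truth_table(self) -> pd.DataFrame:
        """Long-form truth: one row per (dyad, allele, transmission)."""
        rows = []
        for allele in ALLELES:
            mask = self.dyad_in_allele[allele]
            for trans, f in (("maternal", self.f_maternal[allele]),
                             ("paternal", self.f_paternal[allele])):
                rows.append(pd.DataFrame({
                    "pos": self.dyad_pos[mask] + 1,  # 1-based
                    "allele": allele,
                    "transmission": trans,
                    "f": f[mask],
                    "regime": self.dyad_regime[mask],
                }))
        return pd.concat(rows, ignore_index=True)


def _spawn_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(s) for s in stream]])


def _find_dyads(seq_arr: np.ndarray) -> np.ndarray:
    """0-based start positions p with seq[p:p+2] == 'CG'."""
    if seq_arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((seq_arr[:-1] == "C") & (seq_arr[1:] == "G"))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def build_world(config: SimulationConfig) -> SimulatedWorld:
    """Deterministic function of ``config`` (including its seed)."""
    config.validate()
    rng_genome = _spawn_rng(config.seed, 1)
    rng_genes = _spawn_rng(config.seed, 2)
    rng_snps = _spawn_rng(config.seed, 3)
    rng_truth = _spawn_rng(config.seed, 4)

    ref_arr = _random_sequence(rng_genome, config.genome_length, config.gc_fraction)
    reference = "".join(ref_arr)

    genes = _layout_genes(rng_genes, config)
    meth_genes = frozenset(
        g.gene_id for g in genes
        if rng_truth.random() < config.frac_methylated_genes
    )

    snps = _draw_snps(rng_snps, ref_arr, config)
    allele_seqs = {}
    for allele in ALLELES:
        seq = ref_arr.copy()
        if len(snps):
            seq[snps["pos"].to_numpy()] = snps[allele].to_numpy()
        allele_seqs[allele] = "".join(seq)

    # dyad universe: union over reference and all alleles (SNPs both create
    # and destroy CpG sites, as in real colonies)
    dyad_sets = [_find_dyads(ref_arr)]
    allele_dyads = {}
    for allele in ALLELES:
        d = _find_dyads(np.frombuffer(allele_seqs[allele].encode(), dtype="S1").astype("U1"))
        allele_dyads[allele] = d
        dyad_sets.append(d)
    dyad_pos = np.unique(np.concatenate(dyad_sets))

    in_allele = {
        a: np.isin(dyad_pos, allele_dyads[a], assume_unique=False) for a in ALLELES
    }

    baseline = np.full(dyad_pos.size, config.low_meth_level)
    genic_meth = np.zeros(dyad_pos.size, dtype=bool)
    for g in genes:
        if g.gene_id in meth_genes:
            genic_meth |= (dyad_pos >= g.start) & (dyad_pos < g.end)
    baseline[genic_meth] = config.high_meth_level

    u = rng_truth.random(dyad_pos.size)
    regime = np.full(dyad_pos.size, "baseline", dtype=object)
    regime[u < config.frac_imprinted_loci] = "imprinted"
    regime[(u >= config.frac_imprinted_loci)
           & (u < config.frac_imprinted_loci + config.frac_cis_asm_loci)] = "cis_asm"

    offsets = dict(zip(ALLELES, config.asm_allele_offsets))
    f_mat, f_pat = {}, {}
    imprinted = regime == "imprinted"
    cis = regime == "cis_asm"
    for allele in ALLELES:
        f = baseline.copy()
        f[cis] = np.clip(f[cis] + offsets[allele], 0.0, 1.0)
        fm = f.copy()
        fp = f.copy()
        fp[imprinted] = np.clip(fp[imprinted] + config.imprint_delta, 0.0, 1.0)
        absent = ~in_allele[allele]
        fm[absent] = 0.0
        fp[absent] = 0.0
        f_mat[allele] = fm
        f_pat[allele] = fp

    return SimulatedWorld(
        config=config,
        reference=reference,
        snps=snps,
        allele_seqs=allele_seqs,
        genes=genes,
        methylated_genes=meth_genes,
        dyad_pos=dyad_pos,
        dyad_regime=np.asarray(regime, dtype=object),
        dyad_baseline=baseline,
        dyad_in_allele=in_allele,
        f_maternal=f_mat,
        f_paternal=f_pat,
    )


def _layout_genes(rng: np.random.Generator, config: SimulationConfig) -> List[Gene]:
    genes: List[Gene] = []
    if config.n_genes == 0:
        return genes
    slot = config.genome_length // config.n_genes
    lo, hi = config.exons_per_gene
    for i in range(config.n_genes):
        slot_start = i * slot
        span_len = int(slot * rng.uniform(0.4, 0.8))
        span_start = slot_start + int(rng.uniform(0, slot - span_len))
        n_ex = int(rng.integers(lo, hi + 1))
        chunk = span_len // n_ex
        exons = []
        for j in range(n_ex):
            c0 = span_start + j * chunk
            ex_len = max(10, int(chunk * rng.uniform(0.3, 0.8)))
            ex_start = c0 + int(rng.uniform(0, max(1, chunk - ex_len)))
            exons.append((ex_start, min(ex_start + ex_len, span_start + span_len)))
        # pin gene span to its exon extent so introns are interior
        start, end = exons[0][0], exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(
            gene_id=f"GSIM{i + 1:05d}", chrom=config.chrom_name, strand=strand,
            start=start, end=end, exons=tuple(exons),
        ))
    return genes


def _draw_snps(rng: np.random.Generator, ref_arr: np.ndarray,
               config: SimulationConfig) -> pd.DataFrame:
    hit = rng.random(ref_arr.size) < config.snp_rate
    pos = np.flatnonzero(hit)
    bases = "ACGT"
    rows = []
    for p in pos:
        ref = ref_arr[p]
        alt = rng.choice([b for b in bases if b != ref])
        # segregating pattern over the three alleles: not all identical
        while True:
            pattern = [ref if rng.random() < 0.5 else alt for _ in ALLELES]
            if len(set(pattern)) > 1:
                break
        rows.append((int(p), str(ref), *pattern))
    return pd.DataFrame(rows, columns=["pos", "ref", *ALLELES])


# ---------------------------------------------------------------------------
# count-table emission
# ---------------------------------------------------------------------------

def _mode_classes(mode: str) -> List[Tuple[str, str, float]]:
    """(allele, transmission, pooled read weight) for an embryo pool.

    Fertilized: every embryo is (P1 paternal, Mi maternal), Mi equiprobable.
    Thelytokous: worker (P1, Mi) passes both copies maternally; LOH collapse
    picks either copy with equal odds, leaving the pooled mixture unchanged.
    """
    if mode == FERTILIZED:
        return [("P1", "paternal", 0.5), ("M2", "maternal", 0.25),
                ("M3", "maternal", 0.25)]
    if mode == THELYTOKOUS:
        return [("P1", "maternal", 0.5), ("M2", "maternal", 0.25),
                ("M3", "maternal", 0.25)]
    raise ValueError(f"unknown mode {mode!r}")


def _classify_contexts_vector(seq_arr: np.ndarray, pos: np.ndarray,
                              strand: str) -> np.ndarray:
    """Vectorised CG/CHG/CHH context call for cytosines on one strand."""
    n = seq_arr.size
    ctx = np.full(pos.size, "unknown", dtype=object)
    if strand == "+":
        ok1 = pos + 1 < n
        ok2 = pos + 2 < n
        b1 = np.full(pos.size, "N", dtype=object)
        b2 = np.full(pos.size, "N", dtype=object)
        b1[ok1] = seq_arr[pos[ok1] + 1]
        b2[ok2] = seq_arr[pos[ok2] + 2]
    else:
        ok1 = pos - 1 >= 0
        ok2 = pos - 2 >= 0
        b1 = np.full(pos.size, "N", dtype=object)
        b2 = np.full(pos.size, "N", dtype=object)
        # next base 3' on the minus strand is the complement of seq[pos-1]
        b1[ok1] = np.array([c.translate(_COMPLEMENT) for c in seq_arr[pos[ok1] - 1]],
                           dtype=object)
        b2[ok2] = np.array([c.translate(_COMPLEMENT) for c in seq_arr[pos[ok2] - 2]],
                           dtype=object)
    h = np.array(["A", "C", "T"], dtype=object)
    isg1 = b1 == "G"
    ish1 = np.isin(b1, h)
    isg2 = b2 == "G"
    ish2 = np.isin(b2, h)
    ctx[isg1 & ok1] = "CG"
    ctx[ish1 & isg2 & ok2] = "CHG"
    ctx[ish1 & ish2 & ok2] = "CHH"
    return ctx


def simulate_count_table(
    world: SimulatedWorld,
    mode: str,
    config: Optional[SimulationConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine bisulfite counts for one embryo pool, plus its spike-in.

    Returns ``(counts, control)`` as methratio-style frames with columns
    chrom, pos (1-based), strand, context, meth_reads, total_reads; only
    covered sites (total_reads >= 1) are emitted.
    """
    cfg = config or world.config
    mode_code = MODES.index(mode)
    rng = _spawn_rng(cfg.seed, 10, mode_code)

    ref_arr = np.frombuffer(world.reference.encode(), dtype="S1").astype("U1")
    frames = []
    for strand in ("+", "-"):
        base = "C" if strand == "+" else "G"
        pos = np.flatnonzero(ref_arr == base)  # 0-based
        ctx = _classify_contexts_vector(ref_arr, pos, strand)
        # map each strand site to its CpG dyad (if any) on each allele
        dyad_of_site = pos if strand == "+" else pos - 1
        idx = np.searchsorted(world.dyad_pos, dyad_of_site)
        idx_clip = np.clip(idx, 0, max(0, world.dyad_pos.size - 1))
        has_dyad = (world.dyad_pos.size > 0) & (dyad_of_site >= 0)
        has_dyad = has_dyad & (world.dyad_pos[idx_clip] == dyad_of_site)

        n = rng.poisson(cfg.mean_coverage, size=pos.size)
        k = np.zeros(pos.size, dtype=np.int64)
        remaining = n.copy()
        classes = _mode_classes(mode)
        wsum = 1.0
        for allele, trans, w in classes:
            f_tr = world.f_paternal if trans == "paternal" else world.f_maternal
            f_site = np.zeros(pos.size)
            sel = has_dyad & world.dyad_in_allele[allele][idx_clip]
            f_site[sel] = f_tr[allele][idx_clip[sel]]
            q = f_site * (1 - cfg.overconversion_rate) \
                + (1 - f_site) * (1 - cfg.conversion_rate)
            n_c = rng.binomial(remaining, min(1.0, w / wsum))
            remaining = remaining - n_c
            wsum -= w
            k += rng.binomial(n_c, q)
        covered = n >= 1
        frames.append(pd.DataFrame({
            "chrom": cfg.chrom_name,
            "pos": pos[covered] + 1,
            "strand": strand,
            "context": ctx[covered],
            "meth_reads": k[covered],
            "total_reads": n[covered],
        }))
    counts = pd.concat(frames, ignore_index=True)
    counts = counts.sort_values(["pos", "strand"], kind="mergesort",
                                ignore_index=True)

    control = _simulate_control(cfg, rng)
    return counts, control


def _simulate_control(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Fully unmethylated spike-in: truth f = 0 at every cytosine."""
    if cfg.n_control_sites == 0:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                     "meth_reads", "total_reads"])
    # lambda-like sequence just long enough for the requested cytosine count
    length = int(cfg.n_control_sites / 0.25 * 1.3) + 50
    seq = _random_sequence(_spawn_rng(cfg.seed, 20), length, 0.5)
    pos = np.flatnonzero(seq == "C")[: cfg.n_control_sites]
    ctx = _classify_contexts_vector(seq, pos, "+")
    n = rng.poisson(cfg.mean_coverage, size=pos.size)
    k = rng.binomial(n, 1 - cfg.conversion_rate)
    covered = n >= 1
    return pd.DataFrame({
        "chrom": "lambda_spike",
        "pos": pos[covered] + 1,
        "strand": "+",
        "context": ctx[covered],
        "meth_reads": k[covered],
        "total_reads": n[covered],
    })


# ---------------------------------------------------------------------------
# amplicon clones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clone:
    clone_id: str
    sample: str
    mode: str
    sequence: str


@dataclass
class AmpliconCloneSet:
    """Bisulfite-PCR clones for one region of one sample.

    ``truth`` (clone_id -> (allele, transmission)) is simulation ground truth
    kept out of the clone records themselves; the haplotyping stage never
    reads it.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    reference: str  # region reference subsequence (plus strand)
    assay_strand: str
    clones: List[Clone]
    allele_definitions: pd.DataFrame  # pos (1-based genomic), ref, P1, M2, M3
    truth: Dict[str, Tuple[str, str]] = field(default_factory=dict)


def _draw_embryo_copy(rng: np.random.Generator, mode: str,
                      loh_rate: float) -> Tuple[str, str]:
    """One chromosome copy (allele, transmission) from one embryo."""
    maternal = "M2" if rng.random() < 0.5 else "M3"
    if mode == FERTILIZED:
        pair = [("P1", "paternal"), (maternal, "maternal")]
    elif mode == THELYTOKOUS:
        pair = [("P1", "maternal"), (maternal, "maternal")]
        if rng.random() < loh_rate:  # central-fusion LOH: homozygous collapse
            kept = pair[int(rng.random() < 0.5)]
            pair = [kept, kept]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pair[int(rng.random() < 0.5)]


def simulate_clones(
    world: SimulatedWorld,
    region: Tuple[int, int],
    mode: str,
    n_clones: int,
    config: Optional[SimulationConfig] = None,
    sample: Optional[str] = None,
    assay_strand: str = "+",
) -> AmpliconCloneSet:
    """Simulate sequenced bisulfite-PCR clones for ``region`` (1-based incl.).

    Each clone is one allele copy drawn from the mode's pair distribution;
    its sequence carries that allele's SNPs, Bernoulli(truth f) methylation
    at its intact CpG sites, and bisulfite conversion of every unprotected
    cytosine on the assayed strand.
    """
    cfg = config or world.config
    start1, end1 = region
    if start1 < 1 or end1 > len(world.reference) or start1 > end1:
        raise ValueError(f"region {region} outside genome of length "
                         f"{len(world.reference)}")
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if assay_strand != "+":
        raise NotImplementedError("only plus-strand amplicons are simulated")
    s0, e0 = start1 - 1, end1  # 0-based half-open
    mode_code = MODES.index(mode)
    rng = _spawn_rng(cfg.seed, 30, mode_code, s0, e0)
    sample = sample or f"{mode}_{cfg.chrom_name}_{start1}_{end1}"

    snps = world.snps
    in_region = snps[(snps["pos"] >= s0) & (snps["pos"] < e0)].copy() if len(snps) \
        else snps
    defs = in_region.copy()
    if len(defs):
        defs["pos"] = defs["pos"] + 1  # 1-based genomic

    clones: List[Clone] = []
    truth: Dict[str, Tuple[str, str]] = {}
    for i in range(n_clones):
        allele, trans = _draw_embryo_copy(rng, mode, cfg.loh_rate)
        seq = list(world.allele_seqs[allele][s0:e0])
        f_tr = (world.f_paternal if trans == "paternal" else world.f_maternal)[allele]
        # intact CpG dyads of this allele with C inside the region
        mask = world.dyad_in_allele[allele]
        dy = world.dyad_pos[mask]
        fvals = f_tr[mask]
        sel = (dy >= s0) & (dy < e0)
        protected = set()
        for p, f in zip(dy[sel], fvals[sel]):
            if rng.random() < f:  # methylated molecule at this CpG
                if rng.random() >= cfg.overconversion_rate:
                    protected.add(int(p) - s0)
        for j, b in enumerate(seq):
            if b == "C" and j not in protected:
                if rng.random() < cfg.conversion_rate:
                    seq[j] = "T"
        clone_id = f"{sample}_clone{i + 1:03d}"
        clones.append(Clone(clone_id, sample, mode, "".join(seq)))
        truth[clone_id] = (allele, trans)

    return AmpliconCloneSet(
        chrom=cfg.chrom_name, start=start1, end=end1,
        reference=world.reference[s0:e0], assay_strand=assay_strand,
        clones=clones, allele_definitions=defs, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (all plain text)
# ---------------------------------------------------------------------------

def write_world(world: SimulatedWorld, outdir) -> Dict[str, Path]:
    """Write reference FASTA, haplotype TSV, gene GFF3 and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "haplotypes": outdir / "haplotypes.tsv",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{world.config.chrom_name}\n")
        seq = world.reference
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    hap = world.snps.copy()
    if len(hap):
        hap["pos"] = hap["pos"] + 1
    hap.rename(columns={"pos": "POS", "ref": "REF"}).to_csv(
        paths["haplotypes"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in world.genes:
            fh.write("\t".join([
                g.chrom, "capemeth_sim", "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]) + "\n")
            for j, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([
                    g.chrom, "capemeth_sim", "exon", str(s + 1), str(e), ".",
                    g.strand, ".", f"ID={g.gene_id}.e{j};Parent={g.gene_id}",
                ]) + "\n")
    world.truth_table().to_csv(paths["truth"], sep="\t", index=False,
                               float_format="%.6g")
    return paths


def write_clone_fasta(clone_set: AmpliconCloneSet, path) -> Path:
    """FASTA with 'sample= mode= region=' description tokens per clone."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in clone_set.clones:
            fh.write(
                f">{c.clone_id} sample={c.sample} mode={c.mode} "
                f"region={clone_set.chrom}:{clone_set.start}-{clone_set.end}\n"
            )
            for i in range(0, len(c.sequence), 80):
                fh.write(c.sequence[i:i + 80] + "\n")
    return path
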