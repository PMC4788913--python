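"""Allele haplotyping of bisulfite amplicon clones and the ASM-vs-imprinting call.

Bisulfite conversion reads every unmethylated C as T, so on the assayed
strand a C-allele is observed as {C, T} while A, G and T are observed as
themselves.  A SNP therefore distinguishes two alleles only when their
observation sets are disjoint — G-vs-A SNPs are fully informative, C-vs-T
SNPs are confounded.  Clones are assigned to the unique allele compatible
with every covered informative SNP; assigned clones yield a per-allele ×
per-CpG-site methylation matrix, and comparing the matrices from fertilized
and thelytokous pools separates cis-mediated allele-specific methylation
(methylation follows the haplotype in both modes) from parent-of-origin
imprinting (the paternal-history allele changes methylation with the sex of
the transmitting parent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import chi2_contingency

from .stats import bh_adjust, fisher_exact_2x2

__all__ = [
    "AMBIGUOUS",
    "SnpInfo",
    "AlignedClone",
    "AlleleMethylationMatrix",
    "AsmVerdict",
    "UnalignableCloneError",
    "classify_snp_informativeness",
    "align_clone_bisulfite",
    "assign_clone_allele",
    "allele_methylation_matrix",
    "classify_poe_vs_asm",
    "read_allele_definitions",
]

AMBIGUOUS = "ambiguous"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class UnalignableCloneError(ValueError):
    """Clone could not be aligned above the identity floor."""


def _obs_set(base: str) -> frozenset:
    """Possible read bases after bisulfite conversion of the assayed strand."""
    return frozenset({"C", "T"}) if base == "C" else frozenset({base})


@dataclass(frozen=True)
class SnpInfo:
    """Bisulfite informativeness of one SNP on the assayed strand.

    ``pos`` is 0-based within the region; ``bases`` are per-allele read-strand
    bases; ``pair_status`` maps each differing allele pair to True
    (distinguishable) or False (post-conversion ambiguous).
    """

    pos: int
    bases: Dict[str, str]
    status: str  # informative | partially_informative | confounded
    pair_status: Dict[Tuple[str, str], bool]


def classify_snp_informativeness(
    allele_definitions: pd.DataFrame,
    region_start: int = 1,
    region_length: Optional[int] = None,
    assay_strand: str = "+",
) -> List[SnpInfo]:
    """Classify each SNP's ability to separate alleles after conversion.

    ``allele_definitions`` columns: pos (1-based genomic), one column per
    allele name (plus an optional 'ref' column).  ``region_start`` converts
    genomic to region coordinates.
    """
    alleles = [c for c in allele_definitions.columns if c not in ("pos", "ref")]
    if len(alleles) < 2:
        raise ValueError("need at least two alleles")
    out = []
    for _, row in allele_definitions.iterrows():
        rel = int(row["pos"]) - region_start
        if rel < 0 or (region_length is not None and rel >= region_length):
            raise IndexError(f"SNP at {row['pos']} outside the region")
        bases = {a: str(row[a]).upper() for a in alleles}
        if assay_strand == "-":
            bases = {a: _COMPLEMENT[b] for a, b in bases.items()}
        pair_status: Dict[Tuple[str, str], bool] = {}
        for i, a1 in enumerate(alleles):
            for a2 in alleles[i + 1:]:
                if bases[a1] == bases[a2]:
                    continue  # SNP does not separate this pair at all
                pair_status[(a1, a2)] = _obs_set(bases[a1]).isdisjoint(
                    _obs_set(bases[a2]))
        if not pair_status or not any(pair_status.values()):
            status = "confounded"
        elif all(pair_status.values()):
            status = "informative"
        else:
            status = "partially_informative"
        out.append(SnpInfo(pos=rel, bases=bases, status=status,
                           pair_status=pair_status))
    return out


@dataclass(frozen=True)
class AlignedClone:
    """Per-reference-position read bases (None where the clone has a gap)."""

    bases: Tuple[Optional[str], ...]
    identity: float


def _bisulfite_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            m[x, y] = 1.0 if x == y else -1.0
    m["C", "T"] = 1.0  # reference C matches read T: conversion wildcard
    for x in "ACGTN":
        m["N", x] = 0.0
        m[x, "N"] = 0.0
    return m


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.substitution_matrix = _bisulfite_matrix()
_ALIGNER.open_gap_score = -4.0
_ALIGNER.extend_gap_score = -1.0
_ALIGNER.mode = "global"
try:  # free end gaps (attribute names changed across Biopython releases)
    _ALIGNER.end_insertion_score = 0.0
    _ALIGNER.end_deletion_score = 0.0
except AttributeError:  # pragma: no cover
    _ALIGNER.target_end_gap_score = 0.0
    _ALIGNER.query_end_gap_score = 0.0


def _wildcard_match(ref_base: str, read_base: str) -> bool:
    return read_base == ref_base or (ref_base == "C" and read_base == "T")


def align_clone_bisulfite(
    clone_seq: str,
    region_ref: str,
    min_identity: float = 0.70,
) -> AlignedClone:
    """Map a clone onto the region reference with the C/T wildcard.

    Equal-length clones are first compared ungapped (amplicon sequencing
    rarely produces indels); otherwise a semi-global pairwise alignment with
    free end gaps is used.  Identity counts wildcard matches over aligned
    reference positions; below ``min_identity`` the clone is rejected.
    """
    clone_seq = clone_seq.upper()
    region_ref = region_ref.upper()
    n = len(region_ref)
    if not (0.8 * n <= len(clone_seq) <= 1.2 * n):
        raise UnalignableCloneError(
            f"clone length {len(clone_seq)} outside ±20% of region {n}")
    if len(clone_seq) == n:
        matches = sum(_wildcard_match(r, c) for r, c in zip(region_ref, clone_seq))
        identity = matches / n
        if identity >= min_identity:
            return AlignedClone(bases=tuple(clone_seq), identity=identity)
    aln = _ALIGNER.align(region_ref, clone_seq)[0]
    bases: List[Optional[str]] = [None] * n
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            bases[ts + off] = clone_seq[qs + off]
    covered = [(r, b) for r, b in zip(region_ref, bases) if b is not None]
    if not covered:
        raise UnalignableCloneError("clone aligns to no reference position")
    matches = sum(_wildcard_match(r, b) for r, b in covered)
    identity = matches / len(covered)
    if identity < min_identity:
        raise UnalignableCloneError(
            f"alignment identity {identity:.2f} below floor {min_identity}")
    return AlignedClone(bases=tuple(bases), identity=identity)


def assign_clone_allele(
    aligned: AlignedClone,
    snp_info: Sequence[SnpInfo],
    min_informative: int = 1,
) -> str:
    """Assign a clone to the unique allele compatible at informative SNPs.

    Ambiguity (0 or >=2 compatible alleles, or too few covered informative
    SNPs) is a value, not an error.
    """
    usable = [s for s in snp_info
              if s.status != "confounded" and aligned.bases[s.pos] is not None]
    if len(usable) < min_informative:
        return AMBIGUOUS
    alleles = list(usable[0].bases) if usable else []
    compatible = []
    for allele in alleles:
        ok = all(aligned.bases[s.pos] in _obs_set(s.bases[allele]) for s in usable)
        if ok:
            compatible.append(allele)
    return compatible[0] if len(compatible) == 1 else AMBIGUOUS


@dataclass
class AlleleMethylationMatrix:
    """Per-allele × per-CpG-site methylation calls from assigned clones.

    Sites destroyed by a SNP on an allele are masked for that allele and
    carry no calls.  ``overall_pct`` uses the fixed possible-CpG-site
    denominator (methylated calls / (possible sites × assigned clones)).
    """

    alleles: Tuple[str, ...]
    site_pos: np.ndarray  # 0-based region positions of the CpG cytosines
    meth: np.ndarray      # (A, S) methylated-call counts
    calls: np.ndarray     # (A, S) total calls
    masked: np.ndarray    # (A, S) bool
    n_clones: Dict[str, int]
    n_ambiguous: int = 0
    n_unaligned: int = 0

    def fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.meth / self.calls
        f[self.masked] = np.nan
        return f

    def pooled_counts(self) -> Dict[str, Tuple[int, int]]:
        """allele -> (methylated calls, total calls) over unmasked sites."""
        out = {}
        for i, a in enumerate(self.alleles):
            keep = ~self.masked[i]
            out[a] = (int(self.meth[i, keep].sum()), int(self.calls[i, keep].sum()))
        return out

    def overall_pct(self) -> Dict[str, float]:
        n_sites = len(self.site_pos)
        out = {}
        for i, a in enumerate(self.alleles):
            denom = n_sites * self.n_clones.get(a, 0)
            out[a] = 100.0 * float(self.meth[i].sum()) / denom if denom else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.alleles):
            for j, p in enumerate(self.site_pos):
                rows.append({
                    "allele": a, "site_pos": int(p) + 1,
                    "n_clones": int(self.calls[i, j]),
                    "meth_fraction": float(self.meth[i, j] / self.calls[i, j])
                    if self.calls[i, j] else float("nan"),
                    "masked": bool(self.masked[i, j]),
                })
        return pd.DataFrame(rows)

    @classmethod
    def from_pooled(cls, counts_by_allele: Mapping[str, Tuple[int, int]]
                    ) -> "AlleleMethylationMatrix":
        """Build a single-cell-per-allele matrix from pooled (meth, total)."""
        alleles = tuple(counts_by_allele)
        meth = np.array([[counts_by_allele[a][0]] for a in alleles], dtype=float)
        calls = np.array([[counts_by_allele[a][1]] for a in alleles], dtype=float)
        return cls(alleles=alleles, site_pos=np.array([0]), meth=meth,
                   calls=calls, masked=np.zeros_like(meth, dtype=bool),
                   n_clones={a: int(calls[i, 0]) for i, a in enumerate(alleles)})


def _region_cg_sites(region_ref: str) -> np.ndarray:
    arr = np.frombuffer(region_ref.upper().encode(), dtype="S1").astype("U1")
    return np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G")) \
        if arr.size >= 2 else np.empty(0, dtype=np.int64)


def allele_methylation_matrix(
    aligned_clones: Mapping[str, AlignedClone],
    assignments: Mapping[str, str],
    allele_definitions: pd.DataFrame,
    region_ref: str,
    region_start: int = 1,
    n_unaligned: int = 0,
) -> AlleleMethylationMatrix:
    """Tabulate per-allele per-site methylation over assigned clones.

    CpG sites are taken from the region reference (possible sites), then
    per-allele SNP edits mask sites an allele cannot methylate.  A call is
    methylated when the read shows C at the CpG cytosine, unmethylated when
    it shows T; any other base (or a gap) yields no call.
    """
    alleles = tuple(c for c in allele_definitions.columns if c not in ("pos", "ref"))
    if not alleles:
        raise ValueError("allele definitions carry no allele columns")
    sites = _region_cg_sites(region_ref)
    # extend the possible-site set with CpGs created by allele SNPs
    allele_seq = {}
    for a in alleles:
        seq = list(region_ref.upper())
        for _, row in allele_definitions.iterrows():
            rel = int(row["pos"]) - region_start
            if 0 <= rel < len(seq):
                seq[rel] = str(row[a]).upper()
        allele_seq[a] = "".join(seq)
    extra = sorted(set(int(p) for a in alleles for p in _region_cg_sites(allele_seq[a]))
                   - set(int(p) for p in sites))
    if extra:
        sites = np.sort(np.concatenate([sites, np.array(extra, dtype=np.int64)]))

    A, S = len(alleles), len(sites)
    meth = np.zeros((A, S))
    calls = np.zeros((A, S))
    masked = np.zeros((A, S), dtype=bool)
    for i, a in enumerate(alleles):
        seq = allele_seq[a]
        for j, p in enumerate(sites):
            if not (p + 1 < len(seq) and seq[p] == "C" and seq[p + 1] == "G"):
                masked[i, j] = True

    n_clones = {a: 0 for a in alleles}
    n_ambiguous = 0
    for clone_id, aligned in aligned_clones.items():
        allele = assignments.get(clone_id, AMBIGUOUS)
        if allele == AMBIGUOUS or allele not in alleles:
            n_ambiguous += 1
            continue
        i = alleles.index(allele)
        n_clones[allele] += 1
        for j, p in enumerate(sites):
            if masked[i, j]:
                continue
            b = aligned.bases[p]
            if b == "C":
                meth[i, j] += 1
                calls[i, j] += 1
            elif b == "T":
                calls[i, j] += 1

    if sum(n_clones.values()) == 0:
        raise ValueError("no clones could be assigned to an allele")
    return AlleleMethylationMatrix(
        alleles=alleles, site_pos=sites, meth=meth, calls=calls, masked=masked,
        n_clones=n_clones, n_ambiguous=n_ambiguous, n_unaligned=n_unaligned)


@dataclass(frozen=True)
class AsmVerdict:
    """Locus-level call separating cis-ASM from parent-of-origin imprinting."""

    verdict: str  # cis_asm | parent_of_origin | mixed | inconclusive | insufficient_data
    cross_mode_p: Dict[str, float]
    cross_mode_q: Dict[str, float]
    heterogeneity_p: Dict[str, float]
    delta_pct: Dict[str, float]  # fertilized minus thelytokous, percent
    calls_per_cell: Dict[str, Tuple[int, int]]  # "allele/mode" -> (meth, total)
    alpha: float
    min_calls: int


def _heterogeneity_p(pooled: Mapping[str, Tuple[int, int]]) -> float:
    """Pearson chi-square on the alleles × (meth, unmeth) table."""
    table = np.array([[m, t - m] for m, t in pooled.values()], dtype=float)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return 1.0
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(p)


def classify_poe_vs_asm(
    matrix_fertilized: AlleleMethylationMatrix,
    matrix_thelytokous: AlleleMethylationMatrix,
    paternal_history_allele: str = "P1",
    alpha: float = 0.05,
    min_calls: int = 30,
) -> AsmVerdict:
    """Decide cis-ASM vs parent-of-origin from the two mode matrices.

    Rule: with every allele-mode cell holding >= ``min_calls`` pooled calls,
    (i) per-allele cross-mode Fisher tests (BH-adjusted across alleles)
    probe transmission-sex dependence, and (ii) per-mode allele-heterogeneity
    chi-squares probe haplotype dependence.  cis_asm = heterogeneity in both
    modes with no cross-mode shift; parent_of_origin = the paternal-history
    allele shifts across modes more than any maternal allele; mixed = both
    signatures; otherwise inconclusive.
    """
    pooled_f = matrix_fertilized.pooled_counts()
    pooled_t = matrix_thelytokous.pooled_counts()
    if set(pooled_f) != set(pooled_t):
        raise ValueError("allele sets differ between modes")
    alleles = list(pooled_f)
    if paternal_history_allele not in alleles:
        raise ValueError(f"unknown paternal-history allele {paternal_history_allele}")

    cells = {}
    insufficient = False
    for a in alleles:
        cells[f"{a}/fertilized"] = pooled_f[a]
        cells[f"{a}/thelytokous"] = pooled_t[a]
        if pooled_f[a][1] < min_calls or pooled_t[a][1] < min_calls:
            insufficient = True

    p_cross = {}
    delta = {}
    for a in alleles:
        mf, tf = pooled_f[a]
        mt, tt = pooled_t[a]
        p_cross[a] = fisher_exact_2x2(mf, tf - mf, mt, tt - mt) \
            if tf and tt else 1.0
        pf = 100.0 * mf / tf if tf else float("nan")
        pt = 100.0 * mt / tt if tt else float("nan")
        delta[a] = pf - pt
    q_vals = bh_adjust([p_cross[a] for a in alleles])
    q_cross = dict(zip(alleles, (float(q) for q in q_vals)))

    het = {
        "fertilized": _heterogeneity_p(pooled_f),
        "thelytokous": _heterogeneity_p(pooled_t),
    }

    if insufficient:
        verdict = "insufficient_data"
    else:
        any_cross = any(q_cross[a] < alpha for a in alleles)
        cis_flag = het["fertilized"] < alpha and het["thelytokous"] < alpha
        maternal = [a for a in alleles if a != paternal_history_allele]
        pat_delta = abs(delta[paternal_history_allele])
        poe_flag = (q_cross[paternal_history_allele] < alpha
                    and all(pat_delta > abs(delta[a]) for a in maternal))
        if cis_flag and poe_flag:
            verdict = "mixed"
        elif cis_flag and not any_cross:
            verdict = "cis_asm"
        elif poe_flag:
            verdict = "parent_of_origin"
        else:
            verdict = "inconclusive"

    return AsmVerdict(
        verdict=verdict, cross_mode_p=p_cross, cross_mode_q=q_cross,
        heterogeneity_p=het, delta_pct=delta, calls_per_cell=cells,
        alpha=alpha, min_calls=min_calls)


def read_allele_definitions(path) -> pd.DataFrame:
    """Allele-definition TSV: pos (1-based), optional ref, one column/allele."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if "pos" not in df.columns:
        raise ValueError("allele definitions need a 'pos' column")
    return df
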