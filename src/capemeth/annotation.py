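"""Gene-model handling and gene-level aggregation of differential sites.

Differentially methylated sites are located as exonic, intronic or
intergenic (exon beats intron when genes overlap; among equal categories the
gene with the smaller start, then the lexicographically smaller id, wins).
Hypermethylated sites are then aggregated per gene and per direction.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gffutils
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeAnnotation",
    "GeneMethylSummary",
    "AnnotationFormatError",
    "load_models",
    "annotation_from_genes",
    "locate_site",
    "context_partition",
    "aggregate_gene_hypermethylation",
]


class AnnotationFormatError(ValueError):
    """Malformed gene models (orphan exon, exon outside its gene span, ...)."""


@dataclass(frozen=True)
class _GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int
    exons: Tuple[Tuple[int, int], ...]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        ex = sorted(self.exons)
        out = []
        prev = self.start
        for s, e in ex:
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < self.end:
            out.append((prev, self.end))
        return tuple(out)


class GenomeAnnotation:
    """Gene models with fast interval lookup (exon trees + span trees)."""

    def __init__(self, genes: List[_GeneRecord]):
        self.genes: Dict[str, _GeneRecord] = {}
        self._exon_trees: Dict[str, IntervalTree] = {}
        self._span_trees: Dict[str, IntervalTree] = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            if g.gene_id in self.genes:
                raise AnnotationFormatError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            st = self._span_trees.setdefault(g.chrom, IntervalTree())
            st[g.start:g.end] = g.gene_id
            et = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                if s < g.start or e > g.end:
                    raise AnnotationFormatError(
                        f"exon [{s},{e}) outside gene span of {g.gene_id}")
                if e > s:
                    et[s:e] = g.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> List[str]:
        return list(self.genes)


def annotation_from_genes(genes) -> GenomeAnnotation:
    """Build an annotation directly from simulator Gene records."""
    recs = [_GeneRecord(g.gene_id, g.chrom, g.strand, g.start, g.end,
                        tuple(g.exons)) for g in genes]
    return GenomeAnnotation(recs)


def load_models(gff_path) -> GenomeAnnotation:
    """Parse a GFF3 with gene and exon features linked by ID/Parent."""
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(str(gff_path), dbfn=tmp.name, force=True,
                                keep_order=True, merge_strategy="error")
        gene_feats = {f.id: f for f in db.features_of_type("gene")}
        exons_by_gene: Dict[str, List[Tuple[int, int]]] = {g: [] for g in gene_feats}
        for ex in db.features_of_type("exon"):
            parents = ex.attributes.get("Parent", [])
            parent = next((p for p in parents if p in gene_feats), None)
            if parent is None:
                raise AnnotationFormatError(
                    f"orphan exon {ex.id or ex.start} (Parent={parents})")
            exons_by_gene[parent].append((ex.start - 1, ex.end))

    recs = []
    for gid, f in gene_feats.items():
        start, end = f.start - 1, f.end
        exons = sorted(exons_by_gene[gid])
        for s, e in exons:
            if s < start or e > end:
                raise AnnotationFormatError(
                    f"exon [{s + 1},{e}] outside gene span of {gid}")
        recs.append(_GeneRecord(gid, f.seqid, f.strand, start, end, tuple(exons)))
    return GenomeAnnotation(recs)


def locate_site(chrom: str, pos: int, annotation: GenomeAnnotation
                ) -> Tuple[str, Optional[str]]:
    """Category (exon / intron / intergenic) and gene id of a 1-based site."""
    i = pos - 1

    def best(tree: Optional[IntervalTree]):
        if tree is None:
            return None
        hits = tree[i]
        if not hits:
            return None
        gids = sorted(hits, key=lambda iv: (annotation.genes[iv.data].start,
                                            iv.data))
        return gids[0].data

    gid = best(annotation._exon_trees.get(chrom))
    if gid is not None:
        return "exon", gid
    gid = best(annotation._span_trees.get(chrom))
    if gid is not None:
        return "intron", gid
    return "intergenic", None


def context_partition(diff: pd.DataFrame, annotation: GenomeAnnotation
                      ) -> Dict[str, Dict[str, int]]:
    """Exon/intron/intergenic counts of hypermethylated sites per direction.

    Returns ``{direction: {"exon": n, "intron": n, "intergenic": n}}`` for
    directions 'a', 'b' and 'both' (their union).
    """
    out = {d: {"exon": 0, "intron": 0, "intergenic": 0} for d in ("a", "b", "both")}
    hyper = diff[diff["hyper_in"].isin(["a", "b"])]
    for _, row in hyper.iterrows():
        cat, _ = locate_site(row["chrom"], int(row["pos"]), annotation)
        d = row["hyper_in"]
        out[d][cat] += 1
        out["both"][cat] += 1
    return out


@dataclass(frozen=True)
class GeneMethylSummary:
    gene_id: str
    n_hyper_a: int
    n_hyper_b: int
    region_bp: int  # span (max - min + 1) of the gene's hypermethylated sites
    mean_abs_diff: float


def aggregate_gene_hypermethylation(
    diff: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_sites: int = 4,
) -> Tuple[List[GeneMethylSummary], Tuple[int, int, int]]:
    """Per-gene hypermethylated-site counts, top-gene list and gene overlap.

    Returns ``(top_genes, (n_genes_with_a, n_genes_with_b, n_genes_both))``.
    The top list keeps genes with max(n_hyper_a, n_hyper_b) >= min_sites,
    sorted by that count then mean |diff| descending (id as final tie-break,
    so ordering is deterministic).
    """
    per_gene: Dict[str, Dict[str, list]] = {}
    hyper = diff[diff["hyper_in"].isin(["a", "b"])]
    for _, row in hyper.iterrows():
        cat, gid = locate_site(row["chrom"], int(row["pos"]), annotation)
        if gid is None:
            continue  # intergenic sites are never gene-assigned
        rec = per_gene.setdefault(gid, {"a": [], "b": [], "pos": [], "diff": []})
        rec[row["hyper_in"]].append(int(row["pos"]))
        rec["pos"].append(int(row["pos"]))
        rec["diff"].append(abs(float(row["diff_pct"])))

    summaries = []
    genes_a = genes_b = genes_both = 0
    for gid in sorted(per_gene):
        rec = per_gene[gid]
        na, nb = len(rec["a"]), len(rec["b"])
        genes_a += na > 0
        genes_b += nb > 0
        genes_both += (na > 0) and (nb > 0)
        summaries.append(GeneMethylSummary(
            gene_id=gid, n_hyper_a=na, n_hyper_b=nb,
            region_bp=max(rec["pos"]) - min(rec["pos"]) + 1,
            mean_abs_diff=sum(rec["diff"]) / len(rec["diff"]),
        ))

    top = [s for s in summaries if max(s.n_hyper_a, s.n_hyper_b) >= min_sites]
    top.sort(key=lambda s: (-max(s.n_hyper_a, s.n_hyper_b), -s.mean_abs_diff,
                            s.gene_id))
    return top, (genes_a, genes_b, genes_both)


def write_gene_summary(top: List[GeneMethylSummary], path) -> Path:
    path = Path(path)
    df = pd.DataFrame([{
        "gene_id": s.gene_id, "n_hyper_a": s.n_hyper_a, "n_hyper_b": s.n_hyper_b,
        "region_bp": s.region_bp, "mean_abs_diff": round(s.mean_abs_diff, 6),
    } for s in top])
    df.to_csv(path, sep="\t", index=False)
    return path
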