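"""Conversion-rate estimation, context classification and methylation calling.

A cytosine is called methylated when the fraction of non-converted reads at
the site is significantly above the background non-conversion rate measured
in the unmethylated spike-in control, by a one-sided binomial test with
Benjamini–Hochberg correction across all covered sites of the sample.

Cytosines are counted per strand; the two cytosines of a symmetric CpG are
separate sites throughout.  Internal coordinates are 0-based half-open; all
I/O is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import bh_adjust, binomial_tail

__all__ = [
    "COUNT_COLUMNS",
    "CALL_COLUMNS",
    "ConversionEstimate",
    "ContextSummary",
    "MethylomeSummary",
    "OverlapSummary",
    "InvalidSiteError",
    "read_count_table",
    "write_count_table",
    "read_call_table",
    "write_call_table",
    "estimate_conversion_rate",
    "classify_context",
    "genome_context_totals",
    "call_sites",
    "summarize_methylome",
    "overlap_calls",
]

COUNT_COLUMNS = ["chrom", "pos", "strand", "context", "meth_reads", "total_reads"]
CALL_COLUMNS = COUNT_COLUMNS + ["p_value", "q_value", "is_methylated",
                                "meth_freq", "in_window"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class InvalidSiteError(ValueError):
    """The queried base is not a cytosine on the requested strand."""


@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite conversion rate from the spike-in: converted / total reads."""

    rate: float
    converted: int
    total: int


def read_count_table(path) -> pd.DataFrame:
    """Read a methratio-style count TSV ('#'-prefixed header line)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns {missing}")
    df = df[list(df.columns)]
    _validate_counts(df)
    return df


def _validate_counts(df: pd.DataFrame) -> None:
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValueError("meth_reads exceeds total_reads")
    if (df["meth_reads"] < 0).any() or (df["total_reads"] < 0).any():
        raise ValueError("negative read counts")
    if df.duplicated(["chrom", "pos", "strand"]).any():
        raise ValueError("duplicate (chrom, pos, strand) rows")


def _write_tsv(df: pd.DataFrame, path, columns) -> Path:
    path = Path(path)
    out = df[columns].copy()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)
    return path


def write_count_table(df: pd.DataFrame, path) -> Path:
    return _write_tsv(df, path, COUNT_COLUMNS)


def write_call_table(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["is_methylated"] = out["is_methylated"].astype(int)
    out["in_window"] = out["in_window"].astype(int)
    return _write_tsv(out, path, CALL_COLUMNS)


def read_call_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    df["is_methylated"] = df["is_methylated"].astype(bool)
    df["in_window"] = df["in_window"].astype(bool)
    return df


def estimate_conversion_rate(control: pd.DataFrame) -> ConversionEstimate:
    """Pooled C-to-T conversion rate over all spike-in read observations."""
    total = int(control["total_reads"].sum()) if len(control) else 0
    if total == 0:
        raise ValueError("control table has no read observations")
    meth = int(control["meth_reads"].sum())
    converted = total - meth
    return ConversionEstimate(rate=converted / total, converted=converted,
                              total=total)


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Sequence context (CG / CHG / CHH) of the cytosine at 1-based ``pos``.

    Strand-aware: on '-' the cytosine sits where the reference shows G and
    its 3' neighbours run leftward, complemented.  Returns 'unknown' within
    2 bp of the contig end (or next to an ambiguous base).
    """
    i = pos - 1
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    if i < 0 or i >= len(reference):
        raise InvalidSiteError(f"position {pos} outside reference")
    base = reference[i].upper()
    want = "C" if strand == "+" else "G"
    if base != want:
        raise InvalidSiteError(
            f"base at {pos}({strand}) is {base}, not a cytosine on that strand")

    def nxt(offset: int) -> Optional[str]:
        j = i + offset if strand == "+" else i - offset
        if j < 0 or j >= len(reference):
            return None
        b = reference[j].upper()
        if b not in "ACGT":
            return None
        return b if strand == "+" else _COMPLEMENT[b]

    b1 = nxt(1)
    if b1 is None:
        return "unknown"
    if b1 == "G":
        return "CG"
    b2 = nxt(2)
    if b2 is None:
        return "unknown"
    return "CHG" if b2 == "G" else "CHH"


def genome_context_totals(reference: Mapping[str, str] | str) -> Dict[str, int]:
    """Per-context cytosine counts over both strands of the whole genome."""
    if isinstance(reference, str):
        reference = {"": reference}
    totals = {"CG": 0, "CHG": 0, "CHH": 0, "unknown": 0}
    for seq in reference.values():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1").astype("U1")
        for strand, base in (("+", "C"), ("-", "G")):
            pos = np.flatnonzero(arr == base)
            from .simulate import _classify_contexts_vector
            ctx = _classify_contexts_vector(arr, pos, strand)
            for c in totals:
                totals[c] += int((ctx == c).sum())
    return totals


def call_sites(
    table: pd.DataFrame,
    rate: ConversionEstimate | float,
    alpha: float = 0.05,
    window: Tuple[int, int] = (2, 30),
) -> pd.DataFrame:
    """Binomial methylation calls with BH correction across the sample.

    p0 = 1 - conversion rate.  Every covered site (total_reads >= 1) is
    tested; ``in_window`` flags coverage within ``window`` for genome-wide
    summaries, and out-of-window sites are retained but flagged.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    r = rate.rate if isinstance(rate, ConversionEstimate) else float(rate)
    p0 = 1.0 - r
    calls = table.copy()
    tested = calls["total_reads"] >= 1
    p = np.ones(len(calls))
    if tested.any():
        p[tested.to_numpy()] = binomial_tail(
            calls.loc[tested, "meth_reads"].to_numpy(),
            calls.loc[tested, "total_reads"].to_numpy(), p0)
    calls["p_value"] = p
    q = np.ones(len(calls))
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(p[tested.to_numpy()])
    calls["q_value"] = q
    calls["is_methylated"] = calls["q_value"] < alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = calls["meth_reads"] / calls["total_reads"]
    calls["meth_freq"] = freq.fillna(0.0)
    lo, hi = window
    calls["in_window"] = (calls["total_reads"] >= lo) & (calls["total_reads"] <= hi)
    return calls


@dataclass(frozen=True)
class ContextSummary:
    context: str
    genome_total: int
    total_covered: int
    total_methylated: int

    @property
    def pct_of_genome_covered(self) -> float:
        return 100.0 * self.total_covered / self.genome_total if self.genome_total else 0.0

    @property
    def pct_methylation(self) -> float:
        return 100.0 * self.total_methylated / self.total_covered if self.total_covered else 0.0


@dataclass(frozen=True)
class MethylomeSummary:
    """Per-context coverage/methylation tallies within the coverage window."""

    contexts: Tuple[ContextSummary, ...]
    window: Tuple[int, int]

    def by_context(self) -> Dict[str, ContextSummary]:
        return {c.context: c for c in self.contexts}

    @property
    def all_cytosines(self) -> ContextSummary:
        return ContextSummary(
            context="all",
            genome_total=sum(c.genome_total for c in self.contexts),
            total_covered=sum(c.total_covered for c in self.contexts),
            total_methylated=sum(c.total_methylated for c in self.contexts),
        )


def summarize_methylome(calls: pd.DataFrame,
                        genome_totals: Mapping[str, int],
                        window: Tuple[int, int] = (2, 30)) -> MethylomeSummary:
    """Per-context summary: covered / methylated counts and percentages.

    Only in-window sites count; percentages are exactly recomputable from
    the reported counts.
    """
    inw = calls[calls["in_window"]]
    out = []
    for ctx in ("CG", "CHG", "CHH"):
        sub = inw[inw["context"] == ctx]
        if len(sub) and ctx not in genome_totals:
            raise ValueError(f"genome total missing for context {ctx}")
        out.append(ContextSummary(
            context=ctx,
            genome_total=int(genome_totals.get(ctx, 0)),
            total_covered=int(len(sub)),
            total_methylated=int(sub["is_methylated"].sum()),
        ))
    return MethylomeSummary(contexts=tuple(out), window=window)


@dataclass(frozen=True)
class OverlapSummary:
    """Two-sample partition of methylated sites (Venn-style tallies).

    ``insufficient_a`` counts sites methylated in sample a whose coverage in
    sample b falls outside the window (and vice versa), mirroring the
    'insufficient coverage to determine methylation' category.
    """

    common: int
    unique_a: int
    unique_b: int
    insufficient_a: int
    insufficient_b: int
    median_freq_common_a: float
    median_freq_common_b: float
    median_freq_unique_a: float
    median_freq_unique_b: float


def _median(x: pd.Series) -> float:
    return float(x.median()) if len(x) else float("nan")


def overlap_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> OverlapSummary:
    """Partition methylated CG-capable sites between two call tables."""
    key = ["chrom", "pos", "strand"]
    a = calls_a[key + ["is_methylated", "in_window", "meth_freq"]]
    b = calls_b[key + ["is_methylated", "in_window", "meth_freq"]]
    m = a.merge(b, on=key, how="outer", suffixes=("_a", "_b"))
    for col in ("is_methylated_a", "in_window_a", "is_methylated_b", "in_window_b"):
        m[col] = m[col].eq(True)  # absent sites count as uncovered/uncalled

    meth_a = m["is_methylated_a"] & m["in_window_a"]
    meth_b = m["is_methylated_b"] & m["in_window_b"]
    common = meth_a & meth_b
    unique_a = meth_a & m["in_window_b"] & ~m["is_methylated_b"]
    unique_b = meth_b & m["in_window_a"] & ~m["is_methylated_a"]
    insufficient_a = meth_a & ~m["in_window_b"]
    insufficient_b = meth_b & ~m["in_window_a"]

    return OverlapSummary(
        common=int(common.sum()),
        unique_a=int(unique_a.sum()),
        unique_b=int(unique_b.sum()),
        insufficient_a=int(insufficient_a.sum()),
        insufficient_b=int(insufficient_b.sum()),
        median_freq_common_a=_median(m.loc[common, "meth_freq_a"]),
        median_freq_common_b=_median(m.loc[common, "meth_freq_b"]),
        median_freq_unique_a=_median(m.loc[unique_a, "meth_freq_a"]),
        median_freq_unique_b=_median(m.loc[unique_b, "meth_freq_b"]),
    )
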