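"""Site-level differential methylation between two pooled samples.

Per shared site with at least ``min_cov`` reads in both samples, a two-sided
Fisher's exact test compares methylated/unmethylated read counts.  A site is
significant when p <= alpha AND the absolute methylation-frequency
difference reaches ``diff_threshold`` percent; significant sites are
labelled hypermethylated in the sample with the higher frequency.  The
difference is computed a - b, so when sample a is the fertilized pool a
positive difference means higher methylation in fertilized embryos.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_exact_2x2, gof_chi2_equal, bh_adjust

__all__ = ["differential_sites", "hyper_counts_and_bias", "DIFF_COLUMNS"]

DIFF_COLUMNS = ["chrom", "pos", "strand", "freq_a_pct", "freq_b_pct",
                "diff_pct", "p_value", "significant", "hyper_in"]


@lru_cache(maxsize=200_000)
def _cached_fisher(a: int, b: int, c: int, d: int) -> float:
    return fisher_exact_2x2(a, b, c, d)


def differential_sites(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_cov: int = 5,
    diff_threshold: float = 25.0,
    alpha: float = 0.05,
    context: Optional[str] = "CG",
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-sample per-site comparison with the coverage and effect filters.

    ``context`` restricts the comparison (CG by default, None for all);
    ``adjust=True`` compares BH-adjusted q-values to alpha instead of raw p
    (off by default: the thresholding convention here is raw p <= alpha).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    key = ["chrom", "pos", "strand"]
    a = counts_a
    b = counts_b
    if context is not None:
        a = a[a["context"] == context]
        b = b[b["context"] == context]
    m = a[key + ["meth_reads", "total_reads"]].merge(
        b[key + ["meth_reads", "total_reads"]], on=key, suffixes=("_a", "_b"))
    m = m[(m["total_reads_a"] >= min_cov) & (m["total_reads_b"] >= min_cov)]
    if m.empty:
        import warnings
        warnings.warn("no shared sites pass the coverage filter")
        return pd.DataFrame(columns=DIFF_COLUMNS)

    ka = m["meth_reads_a"].to_numpy()
    na = m["total_reads_a"].to_numpy()
    kb = m["meth_reads_b"].to_numpy()
    nb = m["total_reads_b"].to_numpy()
    p = np.fromiter(
        (_cached_fisher(int(ka[i]), int(na[i] - ka[i]),
                        int(kb[i]), int(nb[i] - kb[i]))
         for i in range(len(m))),
        dtype=float, count=len(m))

    freq_a = 100.0 * ka / na
    freq_b = 100.0 * kb / nb
    diff = freq_a - freq_b
    crit = bh_adjust(p) if adjust else p
    significant = (crit <= alpha) & (np.abs(diff) >= diff_threshold)
    hyper = np.where(significant & (diff >= diff_threshold), "a",
                     np.where(significant & (diff <= -diff_threshold), "b", "none"))

    out = pd.DataFrame({
        "chrom": m["chrom"].to_numpy(),
        "pos": m["pos"].to_numpy(),
        "strand": m["strand"].to_numpy(),
        "freq_a_pct": freq_a,
        "freq_b_pct": freq_b,
        "diff_pct": diff,
        "p_value": p,
        "significant": significant,
        "hyper_in": hyper,
    })
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort",
                           ignore_index=True)


def hyper_counts_and_bias(
    table: pd.DataFrame,
) -> Tuple[int, int, Optional[TestResult]]:
    """Hypermethylated-site counts per direction and the directional-bias test.

    Returns ``(count_a, count_b, gof)`` where ``gof`` is the 1-df
    equal-expectation goodness-of-fit chi-square, or None when both counts
    are zero (no test possible).
    """
    if len(table):
        count_a = int((table["hyper_in"] == "a").sum())
        count_b = int((table["hyper_in"] == "b").sum())
    else:
        count_a = count_b = 0
    if count_a == 0 and count_b == 0:
        return count_a, count_b, None
    return count_a, count_b, gof_chi2_equal([count_a, count_b])
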