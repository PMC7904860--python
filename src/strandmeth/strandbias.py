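"""Strand-bias quantification and testing.

The strand bias ``f`` of a region in one cell is the number of 5mC
sites detected on the plus strand divided by the total detected on both
strands.  Under active DNMT1 maintenance CpG methylation is symmetric
and ``f`` sits at 0.5; chromosomes that lost maintenance after a
replication round are hemimethylated and push ``f`` toward 0 or 1.

Departures from 0.5 are tested with a binomial likelihood-ratio
(G-)test:

    G = 2 [ n+ ln(f/0.5) + n- ln((1-f)/0.5) ],   p = P(chi2_1 >= G)

with zero-count terms contributing 0.  The chi-square asymptotics are
poor for small totals, so an exact two-sided binomial test is used when
n+ + n- falls below ``exact_threshold`` (default 25).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

#: below this total site count the exact binomial test replaces the G-test
EXACT_THRESHOLD = 25

#: smallest p-value reported; keeps p in (0, 1] even when chi2.sf underflows
_P_FLOOR = 1e-300

BIAS_COLUMNS = ["cell", "region", "allele", "context",
                "n_plus", "n_minus", "f", "pvalue", "significant", "masked"]


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------

def g_statistic(n_plus, n_minus):
    """Binomial G statistic against the symmetric null p = 0.5."""
    n_plus = np.asarray(n_plus, dtype=float)
    n_minus = np.asarray(n_minus, dtype=float)
    # evaluate with the larger count first so G(a, b) == G(b, a) exactly
    hi = np.maximum(n_plus, n_minus)
    lo = np.minimum(n_plus, n_minus)
    n = hi + lo
    with np.errstate(divide="ignore", invalid="ignore"):
        f = hi / n
        t_hi = np.where(hi > 0, hi * np.log(2.0 * f), 0.0)
        t_lo = np.where(lo > 0, lo * np.log(2.0 * (1.0 - f)), 0.0)
    return 2.0 * (t_hi + t_lo)


def lrt_pvalues(
    n_plus,
    n_minus,
    exact_threshold: int = EXACT_THRESHOLD,
) -> np.ndarray:
    """Vectorised strand-bias LRT p-values.

    Entries whose total count is zero come back NaN; callers should
    mask them (``lrt_strand_bias`` raises instead).
    """
    n_plus = np.atleast_1d(np.asarray(n_plus, dtype=np.int64))
    n_minus = np.atleast_1d(np.asarray(n_minus, dtype=np.int64))
    n = n_plus + n_minus
    p = np.full(n_plus.shape, np.nan)
    big = n >= exact_threshold
    if big.any():
        g = g_statistic(n_plus[big], n_minus[big])
        p[big] = np.maximum(stats.chi2.sf(g, df=1), _P_FLOOR)
    small = (~big) & (n > 0)
    for idx in np.flatnonzero(small):
        p[idx] = stats.binomtest(int(n_plus[idx]), int(n[idx]), 0.5).pvalue
    return p


def lrt_strand_bias(
    n_plus: int,
    n_minus: int,
    exact_threshold: int = EXACT_THRESHOLD,
) -> float:
    """p-value for strand asymmetry of one (n+, n-) pair.

    Symmetric in its arguments; raises on a completely empty region.
    """
    if n_plus < 0 or n_minus < 0:
        raise ValueError("counts must be non-negative")
    if n_plus + n_minus < 1:
        raise ValueError("strand-bias test undefined for zero total count")
    return float(lrt_pvalues([n_plus], [n_minus], exact_threshold)[0])


# ---------------------------------------------------------------------------
# strand-bias records
# ---------------------------------------------------------------------------

def _assign_region(calls: pd.DataFrame, grouping: str,
                   chrom_sizes: Optional[Dict[str, int]] = None) -> pd.Series:
    if grouping == "chromosome":
        return calls["chrom"].astype(str)
    if grouping.startswith("bin:"):
        size = int(grouping.split(":", 1)[1])
        if size <= 0:
            raise ValueError("bin size must be positive")
        start = (calls["pos0"] // size) * size
        end = start + size
        if chrom_sizes:
            cap = calls["chrom"].map(chrom_sizes)
            end = np.minimum(end, cap)  # last partial bin kept, truncated
        return (calls["chrom"].astype(str) + ":" + start.astype(str)
                + "-" + end.astype(str))
    raise ValueError(f"unknown grouping {grouping!r}; use 'chromosome' or 'bin:<size>'")


def compute_bias(
    calls: pd.DataFrame,
    grouping: str = "chromosome",
    context: Optional[str] = "CpG",
    allele: Optional[str] = None,
    min_sites: int = 50,
    alpha: float = 0.05,
    chrom_sizes: Optional[Dict[str, int]] = None,
    exact_threshold: int = EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Per (cell, region) strand-bias records from deduplicated calls.

    Parameters
    ----------
    grouping
        ``"chromosome"`` or ``"bin:<size>"`` (0-based half-open bins,
        last partial bin kept).
    context
        Dinucleotide context filter (e.g. ``"CpG"``, ``"CpA"``); None
        keeps everything.
    allele
        ``None`` aggregates over alleles, ``"split"`` groups by allele,
        any label (``"allele1"``...) filters to it.
    min_sites
        Regions with fewer total sites are masked (f still reported)
        rather than dropped, so downstream matrices keep their shape.
    """
    df = calls
    if context is not None:
        df = df[df["context"] == context]
    split_allele = allele == "split"
    if allele is not None and not split_allele:
        df = df[df["allele"] == allele]
    if df.empty:
        warnings.warn("no calls left after filtering; empty strand-bias table",
                      stacklevel=2)
        return pd.DataFrame(columns=BIAS_COLUMNS)
    df = df.copy()
    df["region"] = _assign_region(df, grouping, chrom_sizes)

    keys = ["cell", "region"] + (["allele"] if split_allele else [])
    counts = (df.groupby(keys + ["strand"], observed=True).size()
              .unstack("strand", fill_value=0))
    for s in ("+", "-"):
        if s not in counts.columns:
            counts[s] = 0
    out = counts.reset_index().rename(columns={"+": "n_plus", "-": "n_minus"})
    if not split_allele:
        out["allele"] = allele if allele is not None else "all"
    out["context"] = context if context is not None else "all"

    n = out["n_plus"] + out["n_minus"]
    with np.errstate(invalid="ignore"):
        out["f"] = np.where(n > 0, out["n_plus"] / n, np.nan)
    out["pvalue"] = lrt_pvalues(out["n_plus"].to_numpy(),
                                out["n_minus"].to_numpy(), exact_threshold)
    out["masked"] = n < min_sites
    out["significant"] = (out["pvalue"] < alpha) & ~out["masked"]
    out = out[BIAS_COLUMNS].sort_values(["cell", "region", "allele"],
                                        kind="mergesort").reset_index(drop=True)
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional multiplicity control)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# plus/minus correlation
# ---------------------------------------------------------------------------

def plus_minus_correlation(
    calls: pd.DataFrame,
    grouping: str = "chromosome",
    context: Optional[str] = "CpG",
    min_regions: int = 3,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """Per-cell Pearson correlation of plus vs minus strand 5mC counts.

    The correlation is computed across regions (chromosomes or bins)
    between the per-region plus-strand and minus-strand site counts;
    regions with zero total count are excluded.  Cells with fewer than
    ``min_regions`` usable regions get r = NaN.
    """
    records = compute_bias(calls, grouping=grouping, context=context,
                           min_sites=1, chrom_sizes=chrom_sizes)
    rows = []
    for cell, grp in records.groupby("cell", observed=True):
        use = grp[(grp["n_plus"] + grp["n_minus"]) > 0]
        n_regions = len(use)
        if n_regions < min_regions:
            r = np.nan
        else:
            x = use["n_plus"].to_numpy(float)
            y = use["n_minus"].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = np.nan  # constant vector: correlation undefined
            else:
                r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"cell": cell, "context": context if context else "all",
                     "r": r, "n_regions": n_regions})
    return pd.DataFrame(rows, columns=["cell", "context", "r", "n_regions"])
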