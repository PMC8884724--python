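"""Per-window CpG methylation from bisulfite counts.

Window aggregation takes the unweighted mean of per-CpG fractions
(methylated/total) among sites meeting a coverage floor — each site
contributes one level regardless of its read depth.  A read-weighted
alternative is available behind a flag for sensitivity analysis.
Windows with no qualifying CpG are missing (NaN), never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import Region, TrendResult, region_correlation, stage_trend

__all__ = [
    "window_methylation",
    "window_methylation_matrix",
    "methylation_trend",
    "meth_access_correlation",
]

CPG_COLUMNS = ["chrom", "pos", "methylated", "total"]


def _validate(cpgs: pd.DataFrame) -> None:
    missing = [c for c in CPG_COLUMNS if c not in cpgs.columns]
    if missing:
        raise ValueError(f"CpG table missing columns: {missing}")
    if (cpgs["total"] < 1).any():
        raise ValueError("total_reads must be >= 1")
    if (cpgs["methylated"] > cpgs["total"]).any():
        raise ValueError("methylated reads exceed total reads")
    if (cpgs["methylated"] < 0).any():
        raise ValueError("negative methylated counts")


def window_methylation(
    cpgs: pd.DataFrame,
    region: Region,
    window_size: int = 50,
    min_coverage: int = 1,
    weighted: bool = False,
) -> pd.Series:
    """Per-window methylation fraction for one sample.

    ``cpgs`` has columns chrom, pos (1-based), methylated, total.  Returns
    a Series indexed by window start coordinate (0-based), NaN where no
    CpG passes the coverage floor.
    """
    _validate(cpgs)
    n_win = region.n_windows(window_size)
    starts = region.start + window_size * np.arange(n_win)
    out = pd.Series(np.nan, index=pd.Index(starts, name="window_start"), dtype=float)

    sel = cpgs[
        (cpgs["chrom"] == region.chrom)
        & (cpgs["pos"] - 1 >= region.start)
        & (cpgs["pos"] - 1 < region.end)
        & (cpgs["total"] >= min_coverage)
    ]
    if sel.empty:
        return out
    win = (sel["pos"] - 1 - region.start) // window_size
    if weighted:
        sums = sel.groupby(win)[["methylated", "total"]].sum()
        agg = sums["methylated"] / sums["total"]
    else:
        frac = sel["methylated"] / sel["total"]
        agg = frac.groupby(win).mean()
    out.iloc[agg.index.to_numpy()] = agg.to_numpy()
    return out


def window_methylation_matrix(
    cpgs: pd.DataFrame,
    region: Region,
    window_size: int = 50,
    min_coverage: int = 1,
    weighted: bool = False,
) -> pd.DataFrame:
    """Windows x samples methylation matrix; requires a ``sample_id`` column."""
    if "sample_id" not in cpgs.columns:
        raise ValueError("CpG table missing sample_id column")
    cols = {}
    for sample_id, sub in cpgs.groupby("sample_id", sort=True):
        cols[sample_id] = window_methylation(sub, region, window_size, min_coverage, weighted)
    return pd.DataFrame(cols)


def methylation_trend(
    values, stages, group: str = ""
) -> TrendResult:
    """Stage trend of per-sample methylation summaries (same contract as
    :func:`aisle.quantify.stage_trend`)."""
    return stage_trend(values, stages, group)


def meth_access_correlation(mean_tpm, mean_methylation) -> tuple[float, float]:
    """Pearson r and p between per-subtype mean TPM and mean methylation."""
    return region_correlation(mean_methylation, mean_tpm)
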