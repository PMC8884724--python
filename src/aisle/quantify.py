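"""Window-based tag-per-million quantification and trend statistics.

Regions are tiled left-to-right into fixed-width windows (default 50 bp,
half-open).  A tag is the 5' position of a read/fragment and belongs to
the window containing that position.  Window values are scaled to tags
per million: ``count * 1e6 / library_size``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = [
    "Region",
    "WindowTrack",
    "TrendResult",
    "window_tpm",
    "ecdf_summary",
    "stage_trend",
    "BackgroundResult",
    "background_sample",
    "region_correlation",
]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 0-based half-open
    end: int
    name: str = ""

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"malformed region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_windows(self, window_size: int) -> int:
        if self.length % window_size != 0:
            raise ValueError(
                f"region length {self.length} not divisible by window size {window_size}"
            )
        return self.length // window_size


@dataclass
class WindowTrack:
    """TPM (or methylation) values per window x sample over one region."""

    region: Region
    window_size: int
    values: pd.DataFrame          # index: window start coords; columns: sample ids
    library_sizes: pd.Series      # per sample
    samples: pd.DataFrame         # sample_id, group, stage (integer stage index)

    def __post_init__(self):
        expected = self.region.n_windows(self.window_size)
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} windows, got {len(self.values)}"
            )


def window_tpm(
    tags: np.ndarray | Sequence[int],
    region: Region,
    window_size: int,
    library_size: float,
    *,
    counts: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-window TPM over ``region`` for one sample.

    Either ``tags`` (tag positions; only those inside the region count) or
    pre-binned per-window ``counts`` may be supplied.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n_win = region.n_windows(window_size)
    if counts is not None:
        c = np.asarray(counts, dtype=float)
        if c.shape != (n_win,):
            raise ValueError(f"expected {n_win} window counts, got {c.shape}")
    else:
        pos = np.asarray(tags, dtype=np.int64)
        pos = pos[(pos >= region.start) & (pos < region.end)]
        c = np.bincount((pos - region.start) // window_size, minlength=n_win).astype(float)
    return c * 1e6 / library_size


def ecdf_summary(values: Sequence[float]) -> tuple[Callable[[float], float], dict[str, float]]:
    """Right-continuous ECDF plus quartiles (linear interpolation).

    Returns ``(ecdf, {"q1":..., "median":..., "q3":...})``; the ECDF is
    vectorized over array input.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateDataError("ecdf_summary needs at least one value")
    sorted_v = np.sort(v)
    n = sorted_v.size

    def ecdf(x):
        r = np.searchsorted(sorted_v, np.asarray(x, dtype=float), side="right") / n
        return float(r) if np.ndim(x) == 0 else r

    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return ecdf, {"q1": float(q1), "median": float(q2), "q3": float(q3)}


@dataclass(frozen=True)
class TrendResult:
    slope: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    intercept: float
    n: int
    group: str = ""


def stage_trend(
    values: Sequence[float],
    stages: Sequence[int],
    group: str = "",
) -> TrendResult:
    """OLS of a per-sample summary on the integer stage index.

    Stages are coded as consecutive integers in developmental order.
    Constant response returns slope 0 with p = 1; an exact non-constant
    linear fit returns p = 0.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(stages, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and stages must be equal-length 1-D")
    if np.unique(x).size < 2:
        raise DegenerateDataError("stage_trend needs >=2 distinct stages")
    n = y.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    dof = n - 2
    if dof <= 0 or rss <= 0.0 or np.isclose(rss, 0.0, atol=1e-300):
        p = 1.0 if slope == 0.0 else 0.0
        return TrendResult(slope, 0.0, (slope, slope), p, intercept, n, group)
    se = float(np.sqrt(rss / dof / sxx))
    t = slope / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    tcrit = float(stats.t.ppf(0.975, dof))
    return TrendResult(
        slope, se, (slope - tcrit * se, slope + tcrit * se), p, intercept, n, group
    )


def _allowed_start_intervals(
    chrom_length: int,
    region_length: int,
    exclusions: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Half-open intervals of admissible draw starts (no exclusion overlap)."""
    lo, hi = 0, chrom_length - region_length + 1
    if hi <= lo:
        raise ValueError("region longer than chromosome")
    # a draw starting at s occupies [s, s+L); it overlaps (a,b) iff s in (a-L, b)
    forbidden = sorted(
        (max(lo, a - region_length + 1), min(hi, b)) for a, b in exclusions
    )
    allowed = []
    cursor = lo
    for a, b in forbidden:
        if a > cursor:
            allowed.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < hi:
        allowed.append((cursor, hi))
    return [iv for iv in allowed if iv[1] > iv[0]]


@dataclass(frozen=True)
class BackgroundResult:
    starts: np.ndarray    # draw start coordinates
    values: np.ndarray    # summary per draw
    query_value: float
    p_empirical: float


def background_sample(
    summarize: Callable[[int, int], float],
    chrom_length: int,
    region: Region,
    n_draws: int = 1000,
    seed: int = 0,
    exclusions: Sequence[tuple[int, int]] = (),
) -> BackgroundResult:
    """Length-matched background draws and an add-one empirical p-value.

    ``summarize(start, end)`` computes the same scalar summary used for
    the query region.  Draw starts are sampled uniformly from the parts of
    the chromosome where a length-matched region overlaps neither the
    query nor any exclusion interval.  The empirical p is
    ``(1 + #{draws >= query}) / (n_draws + 1)``.
    """
    L = region.length
    excl = list(exclusions) + [(region.start, region.end)]
    allowed = _allowed_start_intervals(chrom_length, L, excl)
    if not allowed:
        raise ValueError("exclusions leave no room for background draws")
    widths = np.array([b - a for a, b in allowed], dtype=float)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(allowed), size=n_draws, p=widths / widths.sum())
    offsets = rng.random(n_draws)
    starts = np.array(
        [int(allowed[i][0] + offsets[k] * (allowed[i][1] - allowed[i][0]))
         for k, i in enumerate(which)]
    )
    draws = np.array([summarize(int(s), int(s) + L) for s in starts], dtype=float)
    query_value = float(summarize(region.start, region.end))
    p = (1.0 + float(np.sum(draws >= query_value))) / (n_draws + 1.0)
    return BackgroundResult(starts=starts, values=draws, query_value=query_value, p_empirical=p)


def region_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p over paired region summaries."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D")
    if xv.size < 3:
        raise DegenerateDataError("need >=3 paired points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)
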