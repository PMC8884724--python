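"""Super-enhancer calling from chromHMM 15-state segmentations.

A super-enhancer is a maximal run of exactly abutting enhancer-state
segments (states 6 and 7 of the core 15-state model) whose total span is
at least ``min_length`` bp.  Any intervening non-enhancer segment or
coordinate gap breaks the run.  Coordinates are BED-style 0-based
half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChromatinSegment",
    "SuperEnhancer",
    "STATE_MNEMONICS",
    "parse_segmentation",
    "call_superenhancers",
    "enhancer_length_in_region",
    "specificity_profile",
]

#: core 15-state chromHMM mnemonics, by state number
STATE_MNEMONICS = {
    1: "1_TssA", 2: "2_TssAFlnk", 3: "3_TxFlnk", 4: "4_Tx", 5: "5_TxWk",
    6: "6_EnhG", 7: "7_Enh", 8: "8_ZNF/Rpts", 9: "9_Het", 10: "10_TssBiv",
    11: "11_BivFlnk", 12: "12_EnhBiv", 13: "13_ReprPC", 14: "14_ReprPCWk",
    15: "15_Quies",
}

DEFAULT_ENHANCER_STATES = frozenset({6, 7})

_STATE_RE = re.compile(r"^(?:E)?(\d{1,2})(?:_.*)?$")


def state_number(label: str) -> int:
    """Extract the state number from '6_EnhG', 'E6' or '6' dialects."""
    m = _STATE_RE.match(label.strip())
    if not m:
        raise ValueError(f"unrecognized chromatin state label: {label!r}")
    n = int(m.group(1))
    if not 1 <= n <= 15:
        raise ValueError(f"state number out of range 1..15: {label!r}")
    return n


@dataclass(frozen=True)
class ChromatinSegment:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    state: str
    epigenome_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start},{self.end})")
        if self.start < 0:
            raise ValueError("negative start coordinate")
        state_number(self.state)  # validates

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state_num(self) -> int:
        return state_number(self.state)


@dataclass(frozen=True)
class SuperEnhancer:
    chrom: str
    start: int
    end: int
    epigenome_id: str = ""
    members: tuple[ChromatinSegment, ...] = field(default_factory=tuple)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def parse_segmentation(
    stream: TextIO | Iterable[str],
    epigenome_id: str = "",
) -> list[ChromatinSegment]:
    """Parse dense BED4 segmentation lines (chrom, start, end, state).

    Output is sorted by (chrom, start); out-of-order input is accepted
    with a warning.  Malformed lines and empty intervals raise.
    """
    segments = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: expected >=4 BED fields, got {len(fields)}")
        chrom, start, end, state = fields[0], fields[1], fields[2], fields[3]
        try:
            seg = ChromatinSegment(chrom, int(start), int(end), state, epigenome_id)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        segments.append(seg)
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    if ordered != segments:
        logger.warning("segmentation lines out of order; sorting")
    return ordered


def _check_sorted_nonoverlapping(segments: Sequence[ChromatinSegment]) -> None:
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom:
            if b.start < a.start:
                raise ValueError("segments not sorted by start")
            if b.start < a.end:
                raise ValueError(f"overlapping segments at {a.chrom}:{b.start}")


def call_superenhancers(
    segments: Sequence[ChromatinSegment],
    enhancer_states: frozenset[int] | set[int] = DEFAULT_ENHANCER_STATES,
    min_length: int = 3000,
) -> list[SuperEnhancer]:
    """Maximal abutting runs of enhancer-state segments spanning >= min_length.

    A run extends while the next segment is on the same chromosome, is in
    an enhancer state, and starts exactly where the previous one ends.
    """
    _check_sorted_nonoverlapping(segments)
    out: list[SuperEnhancer] = []
    run: list[ChromatinSegment] = []

    def flush():
        if run and run[-1].end - run[0].start >= min_length:
            out.append(
                SuperEnhancer(
                    chrom=run[0].chrom,
                    start=run[0].start,
                    end=run[-1].end,
                    epigenome_id=run[0].epigenome_id,
                    members=tuple(run),
                )
            )
        run.clear()

    for seg in segments:
        if seg.state_num not in enhancer_states:
            flush()
            continue
        if run and (seg.chrom != run[-1].chrom or seg.start != run[-1].end):
            flush()
        run.append(seg)
    flush()
    return out


def enhancer_length_in_region(
    segments: Sequence[ChromatinSegment],
    region: tuple[str, int, int],
    enhancer_states: frozenset[int] | set[int] = DEFAULT_ENHANCER_STATES,
) -> int:
    """Total bp of enhancer-state segments intersecting a (chrom,start,end) region."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("malformed region")
    total = 0
    for seg in segments:
        if seg.chrom != chrom or seg.state_num not in enhancer_states:
            continue
        total += max(0, min(seg.end, end) - max(seg.start, start))
    return total


def specificity_profile(
    lengths: Mapping[str, int],
    query_epigenome: str,
) -> pd.DataFrame:
    """Rank epigenomes by enhancer length within a region.

    Returns a frame sorted by decreasing length with columns
    ``epigenome_id``, ``enhancer_bp``, ``rank`` (1 = longest, competition
    ranking) and ``frac_with_enhancer`` (constant: share of epigenomes
    with any enhancer overlap).  Raises if the query epigenome is absent.
    """
    if query_epigenome not in lengths:
        raise KeyError(f"query epigenome {query_epigenome!r} not profiled")
    df = pd.DataFrame(
        {"epigenome_id": list(lengths), "enhancer_bp": list(lengths.values())}
    ).sort_values(["enhancer_bp", "epigenome_id"], ascending=[False, True], kind="stable")
    df["rank"] = df["enhancer_bp"].rank(method="min", ascending=False).astype(int)
    n_nonzero = int((df["enhancer_bp"] > 0).sum())
    df["frac_with_enhancer"] = n_nonzero / len(df)
    df["is_query"] = df["epigenome_id"] == query_epigenome
    return df.reset_index(drop=True)
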