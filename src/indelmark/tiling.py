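"""Bait window tiling along the reference, avoiding repeat-rich regions.

Baits are ~20-kb reference windows picked every ~2 Mb (configurable) walking
each chromosome from coordinate 0, the short-arm tip of the assembly.  A
window is acceptable when its overlap with the repeat annotation is at most
``max_repeat_fraction``; unacceptable anchor windows are shifted in 1-kb
steps, alternating downstream/upstream, up to ``shift_limit``.  Anchors with
no acceptable window yield no bait and are logged, mirroring occasional
coverage gaps in manual designs.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


@dataclass
class RepeatTrack:
    """Per-chromosome sorted, merged, 0-based half-open repeat intervals."""

    tracts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: list[tuple[str, int, int]]) -> "RepeatTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if s >= e:
                raise ValueError(f"invalid interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e))
        merged = {c: merge_intervals(v) for c, v in by_chrom.items()}
        return cls(merged)

    def overlap(self, chrom: str, start: int, end: int) -> int:
        """Total repeat bp overlapping [start, end)."""
        tracts = self.tracts.get(chrom, [])
        total = 0
        # tracts are sorted and disjoint; scan the relevant slice
        i = bisect_right([t[1] for t in tracts], start)
        for t0, t1 in tracts[i:]:
            if t0 >= end:
                break
            total += min(end, t1) - max(start, t0)
        return total


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class Bait:
    bait_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    target_anchor_position: int

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("bait sequence length disagrees with coordinates")


def tile_baits(
    reference: dict[str, str],
    repeats: RepeatTrack,
    interval: int = 2_000_000,
    bait_length: int = 20_000,
    max_repeat_fraction: float = 0.2,
    shift_limit: int = 500_000,
    step: int = 1_000,
) -> list[Bait]:
    """Tile bait windows at ideal anchors 0, interval, 2*interval, ... .

    For each anchor the candidate whose start is nearest the anchor and whose
    repeat-overlap fraction is within bound is returned, searching
    alternately +/- in ``step`` increments up to ``shift_limit``; ties (equal
    distance) break toward the smaller coordinate.  Returned baits are
    non-overlapping and sorted.
    """
    if interval <= bait_length:
        raise ValueError("interval must exceed bait_length")
    baits: list[Bait] = []
    for chrom in reference:
        seq = reference[chrom]
        L = len(seq)
        prev_end = 0
        anchor = 0
        while anchor < L:
            chosen = None
            # candidate offsets ordered by |offset|, negative first on ties
            for k in range(0, shift_limit + 1, step):
                for off in ((-k, k) if k else (0,)):
                    s = anchor + off
                    e = s + bait_length
                    if s < prev_end or e > L:
                        continue
                    if repeats.overlap(chrom, s, e) <= max_repeat_fraction * bait_length:
                        chosen = (s, e)
                        break
                if chosen:
                    break
            if chosen:
                s, e = chosen
                baits.append(
                    Bait(
                        f"{chrom}_B{anchor // interval:03d}",
                        chrom,
                        s,
                        e,
                        seq[s:e],
                        anchor,
                    )
                )
                prev_end = e
            else:
                logger.warning(
                    "no acceptable bait window for anchor %s:%d "
                    "(repeat-rich within +/-%d bp)",
                    chrom,
                    anchor,
                    shift_limit,
                )
            anchor += interval
    return baits
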