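"""Locating orthologous regions of bait windows by exact-match anchoring.

Each bait is matched against a target genome by collecting all maximal exact
matches of at least ``word_size`` bp (both strands), then chaining colinear
anchors by total anchored bp (classical sparse chaining).  The best chain
defines the ortholog region; a paralogy guard rejects baits whose best
conflicting chain scores more than ``uniqueness_ratio`` of the winner, and a
minimum-coverage rule rejects baits with too little anchored sequence
(absence or high divergence of the locus in the target).

Anchors are found with a seed-and-extend scheme: every k-mer of the bait
(k = ceil(word_size/2)) is hashed, the genome is scanned at stride
word_size - k + 1, and seed hits are extended to maximality.  Any exact
match of length >= word_size necessarily contains a stride-aligned seed, so
the scheme is exact for the requested word size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from ._seq import revcomp
from .tiling import Bait

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match between a bait and a genome.

    ``gpos`` is the forward-strand coordinate of the leftmost base of the
    genomic span regardless of strand; ``oriented_pos`` is the start in
    strand-oriented coordinates (reverse-complement coordinates on '-'), in
    which chained anchors increase together with bait offsets.
    """

    bait_offset: int
    chrom: str
    gpos: int
    length: int
    strand: str
    oriented_pos: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def _seed_params(word_size: int) -> tuple[int, int]:
    k = (word_size + 1) // 2
    stride = word_size - k + 1
    return k, stride


def find_anchors_batch(
    baits: list[Bait], genome: dict[str, str], word_size: int = 80
) -> dict[str, list[Anchor]]:
    """All maximal exact matches >= word_size between each bait and genome.

    One genome scan serves every bait; results are deduplicated and sorted
    by (bait_offset, chrom, gpos).
    """
    if not baits:
        return {}
    if not (20 <= word_size <= min(b.end - b.start for b in baits)):
        raise ValueError("word_size must be in [20, bait length]")
    k, stride = _seed_params(word_size)

    index: dict[str, list[tuple[int, int]]] = {}
    for bi, bait in enumerate(baits):
        s = bait.sequence
        for off in range(0, len(s) - k + 1):
            index.setdefault(s[off: off + k], []).append((bi, off))

    found: list[set[Anchor]] = [set() for _ in baits]
    # per (bait, chrom, strand, diagonal): genomic spans already explained,
    # so repeated seeds inside one long match extend only once
    seen_spans: dict[tuple, list[tuple[int, int]]] = {}

    for chrom, fwd in genome.items():
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            n = len(seq)
            for i in range(0, n - k + 1, stride):
                hits = index.get(seq[i: i + k])
                if not hits:
                    continue
                for bi, off in hits:
                    key = (bi, chrom, strand, i - off)
                    spans = seen_spans.setdefault(key, [])
                    if any(s0 <= i < s1 for s0, s1 in spans):
                        continue
                    bseq = baits[bi].sequence
                    lo_b, lo_g = off, i
                    while lo_b > 0 and lo_g > 0 and bseq[lo_b - 1] == seq[lo_g - 1]:
                        lo_b -= 1
                        lo_g -= 1
                    hi_b, hi_g = off + k, i + k
                    while (
                        hi_b < len(bseq)
                        and hi_g < n
                        and bseq[hi_b] == seq[hi_g]
                    ):
                        hi_b += 1
                        hi_g += 1
                    spans.append((lo_g, hi_g))
                    length = hi_g - lo_g
                    if length < word_size:
                        continue
                    gpos = lo_g if strand == "+" else L - hi_g
                    found[bi].add(
                        Anchor(lo_b, chrom, gpos, length, strand, lo_g)
                    )
    return {
        baits[bi].bait_id: sorted(
            anchors, key=lambda a: (a.bait_offset, a.chrom, a.gpos, a.strand)
        )
        for bi, anchors in enumerate(found)
    }


def find_anchors(bait: Bait, genome: dict[str, str], word_size: int = 80) -> list[Anchor]:
    return find_anchors_batch([bait], genome, word_size)[bait.bait_id]


@dataclass
class Chain:
    anchors: list[Anchor] = field(default_factory=list)
    score: int = 0  # total anchored bp

    @property
    def chrom(self) -> str | None:
        return self.anchors[0].chrom if self.anchors else None

    @property
    def strand(self) -> str | None:
        return self.anchors[0].strand if self.anchors else None


def _chain_group(anchors: list[Anchor], max_gap: int) -> Chain:
    """Maximum-weight colinear chain within one (chrom, strand) group.

    Consecutive anchors must strictly increase in both coordinate systems
    (starts and ends); they may overlap — chance extension past an InDel
    junction routinely overlaps the neighbouring anchor by a few bp — in
    which case the successor contributes its length minus the larger
    coordinate overlap.  Positive gaps are bounded by ``max_gap`` in both
    systems.  Ties break toward the smaller genome coordinate.
    """
    if not anchors:
        return Chain()
    anchors = sorted(anchors, key=lambda a: (a.bait_offset, a.oriented_pos))
    n = len(anchors)
    max_len = max(a.length for a in anchors)
    dp = [a.length for a in anchors]
    parent = [-1] * n
    for i, a in enumerate(anchors):
        for j in range(i - 1, -1, -1):
            b = anchors[j]
            # bait offsets are sorted; once even the longest possible anchor
            # could not close the gap, no earlier predecessor qualifies
            if a.bait_offset - b.bait_offset > max_gap + max_len:
                break
            if a.bait_offset <= b.bait_offset or a.oriented_pos <= b.oriented_pos:
                continue
            if (
                a.bait_offset + a.length <= b.bait_offset + b.length
                or a.oriented_pos + a.length <= b.oriented_pos + b.length
            ):
                continue
            gap_b = a.bait_offset - (b.bait_offset + b.length)
            gap_g = a.oriented_pos - (b.oriented_pos + b.length)
            if gap_b > max_gap or gap_g > max_gap:
                continue
            weight = a.length - max(0, -min(gap_b, gap_g))
            if weight <= 0:
                continue
            cand = dp[j] + weight
            if cand > dp[i] or (
                cand == dp[i]
                and parent[i] >= 0
                and b.oriented_pos < anchors[parent[i]].oriented_pos
            ):
                dp[i] = cand
                parent[i] = j
    best = max(range(n), key=lambda i: (dp[i], -anchors[i].oriented_pos))
    chain: list[Anchor] = []
    i = best
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return Chain(chain, dp[best])


def chain_anchors(
    anchors: list[Anchor],
    max_gap_ratio: float = 0.25,
    bait_length: int | None = None,
) -> tuple[Chain, int]:
    """Best colinear chain over all (chromosome, strand) groups and the score
    of the best chain conflicting with it (paralogy signal).

    ``max_gap_ratio`` bounds the bait/genome gap between consecutive chained
    anchors as a fraction of the bait length.
    """
    if not anchors:
        return Chain(), 0
    if bait_length is None:
        bait_length = max(a.bait_offset + a.length for a in anchors)
    max_gap = int(max_gap_ratio * bait_length)

    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom, a.strand), []).append(a)

    chains = {key: _chain_group(g, max_gap) for key, g in groups.items()}
    best_key = min(
        chains,
        key=lambda k: (-chains[k].score, chains[k].anchors[0].gpos, k),
    )
    best = chains[best_key]
    second = 0
    for key, ch in chains.items():
        if key != best_key:
            second = max(second, ch.score)
    remaining = [a for a in groups[best_key] if a not in best.anchors]
    if remaining:
        second = max(second, _chain_group(remaining, max_gap).score)
    return best, second


def _trim_overlaps(chain: list[Anchor]) -> list[Anchor]:
    """Left-trim chained anchors so consecutive anchors are disjoint in both
    coordinate systems (a sub-run of an exact match is still exact; trimmed
    anchors are no longer maximal)."""
    out: list[Anchor] = []
    prev_b_end = prev_o_end = -1
    for a in chain:
        o = max(0, prev_b_end - a.bait_offset, prev_o_end - a.oriented_pos)
        if o:
            a = Anchor(
                a.bait_offset + o,
                a.chrom,
                a.gpos + o if a.strand == "+" else a.gpos,
                a.length - o,
                a.strand,
                a.oriented_pos + o,
            )
        out.append(a)
        prev_b_end = a.bait_offset + a.length
        prev_o_end = a.oriented_pos + a.length
    return out


@dataclass
class OrthologRegion:
    bait_id: str
    accession: str
    chrom: str
    start: int
    end: int
    strand: str
    chain: list[Anchor]
    chain_score: int
    second_best_score: int
    status: str = "ok"  # ok | absent | ambiguous


def extract_ortholog(
    bait: Bait,
    genome: dict[str, str],
    word_size: int = 80,
    uniqueness_ratio: float = 0.5,
    margin: int = 1_000,
    min_coverage: float = 0.1,
    max_gap_ratio: float = 0.25,
    accession: str = "",
    anchors: list[Anchor] | None = None,
) -> OrthologRegion | None:
    """Best-chain ortholog region of the bait in the target genome, padded by
    ``margin``; None when coverage is too low (absent/high divergence) or the
    locus is not unique (best conflicting chain above ``uniqueness_ratio``)."""
    if anchors is None:
        anchors = find_anchors(bait, genome, word_size)
    bait_len = bait.end - bait.start
    chain, second = chain_anchors(anchors, max_gap_ratio, bait_len)
    if chain.score < min_coverage * bait_len:
        logger.info(
            "bait %s absent in %s (chain score %d < %.0f)",
            bait.bait_id, accession, chain.score, min_coverage * bait_len,
        )
        return None
    if second > uniqueness_ratio * chain.score:
        logger.info(
            "bait %s ambiguous in %s (second-best %d / best %d)",
            bait.bait_id, accession, second, chain.score,
        )
        return None
    chrom = chain.chrom
    L = len(genome[chrom])
    trimmed = _trim_overlaps(chain.anchors)
    g_lo = min(a.gpos for a in trimmed)
    g_hi = max(a.gpos + a.length for a in trimmed)
    return OrthologRegion(
        bait.bait_id,
        accession,
        chrom,
        max(0, g_lo - margin),
        min(L, g_hi + margin),
        chain.strand,
        trimmed,
        chain.score,
        second,
    )
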