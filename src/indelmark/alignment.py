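"""Pairwise and reference-projected alignment of baits against ortholog
regions.

Chained anchors (maximal exact matches) are frozen as aligned blocks; the
sequence between consecutive anchors is aligned by global affine-gap dynamic
programming (Gotoh's three-state recurrence), banded around the diagonal
with a band of the segment length difference plus 50.  A gap run of length L
costs ``gap_open + (L - 1) * gap_extend``.  Tracebacks are deterministic: on
ties the diagonal (match/mismatch) state is preferred, then the vertical
(gap-in-genome) state, then the horizontal.

The per-accession pairwise alignments are then stacked on the bait
(reference-pivot construction): columns are keyed by (reference position,
insertion offset); insertion columns from different accessions at the same
reference position are left-aligned and padded, with no attempt to align
insertion content across accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .orthologs import OrthologRegion
from .tiling import Bait

logger = logging.getLogger(__name__)

NEG = -1e15

DEFAULT_SCHEME = {"match": 1, "mismatch": -1, "gap_open": -4, "gap_extend": -1}


class AlignmentError(ValueError):
    pass


def affine_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
    band: int | None = None,
) -> tuple[int, str, str]:
    """Global affine-gap alignment of a vs b.

    Returns (score, gapped_a, gapped_b).  ``band`` limits |j - i| to
    ``band + length difference`` around the diagonal; None aligns the full
    matrix.  N (or any non-identical symbol pair) scores as a mismatch.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        ga = a + "-" * m
        gb = "-" * n + b
        L = max(n, m)
        score = 0 if L == 0 else gap_open + (L - 1) * gap_extend
        return score, ga, gb

    if band is None:
        lo_off, hi_off = n, m  # full matrix
    else:
        lo_off = band + max(0, n - m)
        hi_off = band + max(0, m - n)
    Lo = min(lo_off, n)
    Hi = min(hi_off, m)
    W = Lo + Hi + 1
    if (n + 1) * W > 200_000_000:
        raise AlignmentError(
            f"alignment problem too large ({n} x {m}, band width {W})"
        )

    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    _N = ord("N")

    # bpad[i + k] is b[j - 1] for cell (row i, band index k); 0 = sentinel
    bpad = np.zeros(n + W + 2, dtype=np.uint8)
    bpad[Lo + 1: Lo + 1 + m] = b_arr
    a_ok = a_arr != _N

    M = np.full((n + 1, W), NEG)
    X = np.full((n + 1, W), NEG)
    Y = np.full((n + 1, W), NEG)
    ptrM = np.zeros((n + 1, W), dtype=np.int8)
    ptrX = np.zeros((n + 1, W), dtype=np.int8)

    # j = i + k - Lo for cell (row i, band index k)
    ks = np.arange(W)
    ge = float(gap_extend)
    go = float(gap_open)
    gek = ge * ks

    # row 0
    M[0, Lo] = 0.0
    j0 = ks - Lo
    sel = (j0 >= 1) & (j0 <= m)
    Y[0, sel] = go + (j0[sel] - 1) * ge

    for i in range(1, n + 1):
        # valid j range [0, m] maps to band indices [k_lo, k_hi]
        k_lo = max(0, Lo - i)
        k_hi = min(W - 1, m - i + Lo)
        if k_hi < k_lo:
            continue
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]

        # diagonal predecessor (i-1, j-1) sits at the same band index
        best_prev = np.maximum(np.maximum(prevM, prevX), prevY)
        ptrM[i] = np.where(
            prevM >= best_prev, 0, np.where(prevX >= best_prev, 1, 2)
        )
        bs = bpad[i: i + W]
        sub = np.where(
            (a_arr[i - 1] == bs) & a_ok[i - 1], float(match), float(mismatch)
        )
        Mi = M[i]
        Mi[:] = best_prev + sub
        mk_lo = max(k_lo, Lo - i + 1)  # M needs j >= 1
        Mi[:mk_lo] = NEG
        Mi[k_hi + 1:] = NEG

        # vertical predecessor (i-1, j) sits one band index to the right
        Xi = X[i]
        xm = prevM[1:] + go
        xx = prevX[1:] + ge
        xy = prevY[1:] + go
        Xi[:-1] = np.maximum(np.maximum(xm, xx), xy)
        Xi[-1] = NEG
        ptrX[i, :-1] = np.where(
            xm >= Xi[:-1], 0, np.where(xx >= Xi[:-1], 1, 2)
        )
        Xi[:k_lo] = NEG
        Xi[k_hi + 1:] = NEG
        if i <= Lo:  # left column j=0 boundary cell
            Xi[Lo - i] = go + (i - 1) * ge
            ptrX[i, Lo - i] = 1

        # horizontal moves within the row: prefix-max formulation
        # Y[i][j] = max_{j'<j}( max(M,X)[i][j'] + go + (j-1-j')*ge )
        run = np.maximum.accumulate(np.maximum(Mi, Xi) - gek)
        Yi = Y[i]
        Yi[0] = NEG
        Yi[1:] = go + gek[1:] - ge + run[:-1]
        yk_lo = max(k_lo, Lo - i + 1)  # Y needs j >= 1
        Yi[:yk_lo] = NEG
        Yi[k_hi + 1:] = NEG

    kf = m - n + Lo
    finals = (M[n, kf], X[n, kf], Y[n, kf])
    state = int(np.argmax(finals))  # ties: M > X > Y
    score = finals[state]

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = j - i + Lo
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            state = int(ptrM[i, k])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            state = int(ptrX[i, k])
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            y = Y[i, k]
            km = k - 1
            if km >= 0 and abs(M[i, km] + go - y) < 0.5:
                state = 0
            elif km >= 0 and abs(X[i, km] + go - y) < 0.5:
                state = 1
            else:
                state = 2
            j -= 1
    return int(round(score)), "".join(reversed(out_a)), "".join(reversed(out_b))


@dataclass
class PairwiseAlignment:
    bait_id: str
    accession: str
    aligned_bait: str
    aligned_genome: str
    score: int

    def __post_init__(self):
        if len(self.aligned_bait) != len(self.aligned_genome):
            raise ValueError("gapped rows must have equal length")


def region_sequence(region: OrthologRegion, genome: dict[str, str]) -> str:
    """Region sequence in bait-forward orientation."""
    seq = genome[region.chrom][region.start: region.end]
    return revcomp(seq) if region.strand == "-" else seq


def align_pair(
    bait: Bait,
    region: OrthologRegion,
    genome: dict[str, str],
    scheme: dict | None = None,
    band_pad: int = 50,
    max_segment: int = 50_000,
) -> PairwiseAlignment:
    """Anchor-frozen global alignment of the bait against its ortholog
    region.  Raises AlignmentError when an inter-anchor segment exceeds
    ``max_segment`` bp."""
    sc = dict(DEFAULT_SCHEME)
    if scheme:
        sc.update(scheme)
    rseq = region_sequence(region, genome)
    rlen = len(rseq)
    bseq = bait.sequence

    # anchor coordinates local to the oriented region sequence
    local = []
    for anc in region.chain:
        if region.strand == "+":
            r0 = anc.gpos - region.start
        else:
            r0 = region.end - (anc.gpos + anc.length)
        local.append((anc.bait_offset, r0, anc.length))
    local.sort()

    parts_b: list[str] = []
    parts_g: list[str] = []
    score = 0
    pb = pg = 0
    for bo, ro, ln in local + [(len(bseq), rlen, 0)]:
        seg_b = bseq[pb:bo]
        seg_g = rseq[pg:ro]
        if len(seg_b) > max_segment or len(seg_g) > max_segment:
            raise AlignmentError(
                f"inter-anchor segment exceeds {max_segment} bp "
                f"for {bait.bait_id}/{region.accession}"
            )
        if seg_b or seg_g:
            s, ga, gg = affine_align(
                seg_b,
                seg_g,
                band=band_pad,
                **sc,
            )
            score += s
            parts_b.append(ga)
            parts_g.append(gg)
        if ln:
            anchor_seq = bseq[bo: bo + ln]
            parts_b.append(anchor_seq)
            parts_g.append(anchor_seq)
            score += ln * sc["match"]
        pb, pg = bo + ln, ro + ln
    return PairwiseAlignment(
        bait.bait_id, region.accession, "".join(parts_b), "".join(parts_g), score
    )


@dataclass
class MultiAlignment:
    """Reference-pivot stack of pairwise alignments.

    Columns are keyed (reference position, insertion offset); offset 0
    columns carry the reference base, offsets >= 1 are insertions relative
    to the reference (keyed to the preceding reference position, -1 for
    insertions before the first base).
    """

    bait: Bait
    keys: list[tuple[int, int]]
    reference_row: str
    rows: dict[str, str]
    accession_order: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.keys)

    def degapped(self, accession: str) -> str:
        return self.rows[accession].replace("-", "")


def project_to_reference(
    bait: Bait, pairwise: list[PairwiseAlignment]
) -> MultiAlignment:
    """Stack pairwise alignments of one bait into a reference-projected MSA."""
    seen = set()
    for pw in pairwise:
        if pw.bait_id != bait.bait_id:
            raise ValueError("pairwise alignments must share the bait")
        if pw.accession in seen:
            raise ValueError(f"duplicate accession {pw.accession!r}")
        seen.add(pw.accession)

    n = len(bait.sequence)
    base_sym: dict[str, list[str]] = {}
    ins_sym: dict[str, dict[int, str]] = {}
    max_ins: dict[int, int] = {}
    for pw in pairwise:
        syms = ["-"] * n
        ins: dict[int, list[str]] = {}
        p = 0
        for cb, cg in zip(pw.aligned_bait, pw.aligned_genome):
            if cb != "-":
                syms[p] = cg
                p += 1
            elif cg != "-":
                ins.setdefault(p - 1, []).append(cg)
        if p != n:
            raise ValueError("alignment does not cover the bait")
        base_sym[pw.accession] = syms
        ins_sym[pw.accession] = {k: "".join(v) for k, v in ins.items()}
        for k, v in ins_sym[pw.accession].items():
            max_ins[k] = max(max_ins.get(k, 0), len(v))

    keys: list[tuple[int, int]] = []
    ref_chars: list[str] = []
    row_chars: dict[str, list[str]] = {pw.accession: [] for pw in pairwise}

    def emit_insertions(p: int) -> None:
        k = max_ins.get(p, 0)
        if not k:
            return
        for off in range(1, k + 1):
            keys.append((p, off))
            ref_chars.append("-")
        for acc in row_chars:
            v = ins_sym[acc].get(p, "")
            row_chars[acc].append(v + "-" * (k - len(v)))

    emit_insertions(-1)
    for p in range(n):
        keys.append((p, 0))
        ref_chars.append(bait.sequence[p])
        for acc in row_chars:
            row_chars[acc].append(base_sym[acc][p])
        emit_insertions(p)

    return MultiAlignment(
        bait,
        keys,
        "".join(ref_chars),
        {acc: "".join(chars) for acc, chars in row_chars.items()},
        [pw.accession for pw in pairwise],
    )
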