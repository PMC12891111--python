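"""InDel screening and primer-pair design on reference-projected alignments.

A qualifying site is an InDel where the wild allele differs from *every*
cultivar allele by at least ``min_gap`` (default 20 bp, the agarose
resolvability bound) and where the cultivars themselves are reference-like
(common-InDel rule: variety-specific InDels are rejected).  Primer pairs are
drawn from conserved flanks — alignment blocks where every accession carries
the identical base — under the standard design windows: length 18-25 nt,
GC fraction 0.40-0.60, Tm 50-60 C (target 55), pair Tm difference <= 3 C,
no mononucleotide run of 5+, cultivar products 100-500 bp.  Primer
uniqueness is an exact two-strand occurrence count against the whole
reference.  Markers are named CxxPxxxxx: genome-type letter, two-digit
chromosome, five-digit kb position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from ._seq import count_occurrences, revcomp
from .alignment import MultiAlignment

logger = logging.getLogger(__name__)


@dataclass
class InDelSite:
    bait_id: str
    ref_start: int  # bait-relative, 0-based
    ref_end: int    # end of the reference span touched by the site
    alleles: dict[str, int]  # accession -> net length vs reference (bp)
    event_type: str  # insertion_in_wild | deletion_in_wild | complex
    cultivar_consistent: bool
    wild_vs_all_cultivars_gap: int


def call_indels(
    msa: MultiAlignment,
    wild: str,
    cultivars: list[str],
    merge_gap: int = 3,
) -> list[InDelSite]:
    """Allele-length records for every InDel in the alignment.

    Maximal gap (and insertion) runs per accession become events; events
    whose reference spans lie within ``merge_gap`` matching columns of each
    other are merged into one site.  Runs touching the first or last
    alignment column are alignment-edge artifacts and are ignored.
    """
    keys = msa.keys
    ncol = len(keys)
    events: list[tuple[int, int, str, int]] = []  # (ref_start, ref_end, acc, net)

    for acc, row in msa.rows.items():
        runs: list[tuple[int, int]] = []  # column runs of indel evidence
        start = None
        for ci in range(ncol):
            off0 = keys[ci][1] == 0
            is_event = (off0 and row[ci] == "-") or (not off0 and row[ci] != "-")
            if is_event and start is None:
                start = ci
            elif not is_event and start is not None:
                runs.append((start, ci))
                start = None
        if start is not None:
            runs.append((start, ncol))
        for c0, c1 in runs:
            if c0 == 0 or c1 == ncol:
                continue  # terminal run: edge of the aligned region
            net = 0
            for ci in range(c0, c1):
                if keys[ci][1] == 0:
                    net -= 1  # reference base deleted in this accession
                else:
                    net += 1  # inserted base relative to the reference
            ref_lo = keys[c0][0] + (1 if keys[c0][1] > 0 else 0)
            ref_hi = keys[c1 - 1][0] + 1
            events.append((ref_lo, max(ref_hi, ref_lo), acc, net))

    events.sort(key=lambda e: (e[0], e[1]))
    sites: list[InDelSite] = []
    cluster: list[tuple[int, int, str, int]] = []

    def flush() -> None:
        if not cluster:
            return
        lo = min(e[0] for e in cluster)
        hi = max(e[1] for e in cluster)
        alleles = {acc: 0 for acc in msa.rows}
        for _, _, acc, net in cluster:
            alleles[acc] += net
        w = alleles.get(wild, 0)
        etype = (
            "insertion_in_wild" if w > 0
            else "deletion_in_wild" if w < 0
            else "complex"
        )
        consistent = all(abs(alleles.get(c, 0)) <= 3 for c in cultivars)
        gap = min(abs(w - alleles.get(c, 0)) for c in cultivars) if cultivars else abs(w)
        sites.append(
            InDelSite(msa.bait.bait_id, lo, hi, alleles, etype, consistent, gap)
        )

    cur_end = None
    for ev in events:
        if cur_end is not None and ev[0] <= cur_end + merge_gap:
            cluster.append(ev)
            cur_end = max(cur_end, ev[1])
        else:
            flush()
            cluster = [ev]
            cur_end = ev[1]
    flush()
    sites.sort(key=lambda s: s.ref_start)
    return sites


def screen_indels(sites: list[InDelSite], min_gap: int = 20) -> list[InDelSite]:
    """Keep sites with a >= min_gap wild-vs-every-cultivar length difference
    and a consistent (reference-like) allele across cultivars."""
    kept = []
    for s in sites:
        if s.wild_vs_all_cultivars_gap < min_gap:
            logger.info(
                "site %s:%d rejected: gap %d < %d",
                s.bait_id, s.ref_start, s.wild_vs_all_cultivars_gap, min_gap,
            )
        elif not s.cultivar_consistent:
            logger.info(
                "site %s:%d rejected: InDel not common among cultivars",
                s.bait_id, s.ref_start,
            )
        else:
            kept.append(s)
    return kept


def gc_fraction(sequence: str) -> float:
    """(G + C) / length of an ACGT string."""
    if not sequence:
        raise ValueError("empty sequence")
    if re.search("[^ACGT]", sequence):
        raise ValueError(f"non-ACGT symbol in {sequence!r}")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def melting_temperature(sequence: str) -> float:
    """Long-oligo GC approximation: Tm = 64.9 + 41 * (GC - 16.4) / length."""
    if len(sequence) < 14:
        raise ValueError("Tm formula requires length >= 14 nt")
    gc = sequence.count("G") + sequence.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(sequence)


def _max_mono_run(seq: str) -> int:
    best = run = 1
    for x, y in zip(seq, seq[1:]):
        run = run + 1 if x == y else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class Primer:
    sequence: str
    position: int  # reference coordinate of the 5'-most template base, 0-based
    strand: str
    length: int
    gc_fraction: float
    tm: float
    genome_hit_count: int = 0


@dataclass
class Marker:
    name: str
    chrom: str
    position: int  # 0-based reference coordinate of the InDel site
    forward: Primer
    reverse: Primer
    expected_size: dict[str, int]
    indel_site: InDelSite


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 18
    max_length: int = 25
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (50.0, 60.0)
    tm_target: float = 55.0
    max_tm_difference: float = 3.0
    max_mono_run: int = 4          # no mononucleotide run of 5 or more
    product_range: tuple[int, int] = (100, 500)   # reference and cultivars
    wild_product_range: tuple[int, int] = (50, 2_000)
    min_gap: int = 20


def _conserved_blocks(msa: MultiAlignment) -> list[tuple[int, int]]:
    """Maximal reference intervals where all accessions equal the reference
    base and no accession carries an internal insertion."""
    n = len(msa.bait.sequence)
    conserved = np.ones(n, dtype=bool)
    break_after = np.zeros(n, dtype=bool)
    col_of_ref = {}
    for ci, (p, off) in enumerate(msa.keys):
        if off == 0:
            col_of_ref[p] = ci
        elif 0 <= p < n:
            for row in msa.rows.values():
                if row[ci] != "-":
                    break_after[p] = True
                    break
    for p in range(n):
        ci = col_of_ref[p]
        ref = msa.reference_row[ci]
        if ref not in "ACGT":
            conserved[p] = False
            continue
        for row in msa.rows.values():
            if row[ci] != ref:
                conserved[p] = False
                break
    blocks = []
    s = None
    for p in range(n):
        if not conserved[p]:
            if s is not None:
                blocks.append((s, p))
                s = None
            continue
        if s is None:
            s = p
        if break_after[p]:  # an accession inserts between p and p+1
            blocks.append((s, p + 1))
            s = None
    if s is not None:
        blocks.append((s, n))
    return blocks


@dataclass(frozen=True)
class _Window:
    start: int
    end: int
    seq: str
    tm: float
    dev: float
    gc3: int  # 1 when the 3' base is G or C


def _windows_in(
    blocks: list[tuple[int, int]],
    bait_seq: str,
    lo: int,
    hi: int,
    is_forward: bool,
    c: PrimerConstraints,
) -> list[_Window]:
    out = []
    for b0, b1 in blocks:
        w0, w1 = max(b0, lo), min(b1, hi)
        for s in range(w0, w1):
            for ln in range(c.min_length, c.max_length + 1):
                e = s + ln
                if e > w1:
                    break
                seq = bait_seq[s:e]
                gc = (seq.count("G") + seq.count("C")) / ln
                if not (c.gc_range[0] <= gc <= c.gc_range[1]):
                    continue
                tm = 64.9 + 41.0 * (gc * ln - 16.4) / ln
                if not (c.tm_range[0] <= tm <= c.tm_range[1]):
                    continue
                if _max_mono_run(seq) > c.max_mono_run:
                    continue
                primer = seq if is_forward else revcomp(seq)
                out.append(
                    _Window(
                        s, e, primer, tm, abs(tm - c.tm_target),
                        1 if primer[-1] in "GC" else 0,
                    )
                )
    out.sort(key=lambda w: (w.dev, w.start, w.end))
    return out


def design_primer_pair(
    msa: MultiAlignment,
    site: InDelSite,
    wild: str,
    cultivars: list[str],
    constraints: PrimerConstraints | None = None,
    n_candidates: int = 5,
) -> list[Marker]:
    """Ranked acceptable primer pairs for a screened site (best first).

    Ranking minimizes |Tm_fwd - 55| + |Tm_rev - 55|; ties prefer G/C 3'
    ends, then the smaller reference product, then coordinates.  The marker
    name is left blank (chromosome-level naming happens downstream).
    """
    c = constraints or PrimerConstraints()
    bait = msa.bait
    blocks = _conserved_blocks(msa)
    max_prod = c.product_range[1]
    fwd = _windows_in(
        blocks, bait.sequence,
        max(0, site.ref_start - max_prod), site.ref_start, True, c,
    )
    rev = _windows_in(
        blocks, bait.sequence,
        site.ref_end, min(len(bait.sequence), site.ref_end + max_prod), False, c,
    )
    if not fwd or not rev:
        logger.info(
            "site %s:%d dropped: no conserved primer flank",
            site.bait_id, site.ref_start,
        )
        return []

    # per-accession cumulative non-gap counts over columns, for product sizes
    col_of_ref = {p: ci for ci, (p, off) in enumerate(msa.keys) if off == 0}
    cum: dict[str, np.ndarray] = {}
    for acc, row in msa.rows.items():
        arr = np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
        cum[acc] = np.concatenate(([0], np.cumsum(arr)))

    def product(acc: str, s: int, e: int) -> int:
        c0, c1 = col_of_ref[s], col_of_ref[e - 1]
        return int(cum[acc][c1 + 1] - cum[acc][c0])

    ranked: list[tuple] = []
    worst = float("inf")
    for f in fwd:
        if ranked and len(ranked) >= n_candidates and f.dev > worst:
            break
        for r in rev:
            devsum = f.dev + r.dev
            if len(ranked) >= n_candidates and devsum > worst:
                break
            if abs(f.tm - r.tm) > c.max_tm_difference:
                continue
            ref_size = r.end - f.start
            if not (c.product_range[0] <= ref_size <= c.product_range[1]):
                continue
            sizes = {"__ref__": ref_size}
            ok = True
            for acc in msa.rows:
                sz = product(acc, f.start, r.end)
                sizes[acc] = sz
                if acc == wild:
                    if not (c.wild_product_range[0] <= sz <= c.wild_product_range[1]):
                        ok = False
                        break
                elif acc in cultivars:
                    if not (c.product_range[0] <= sz <= c.product_range[1]):
                        ok = False
                        break
            if not ok:
                continue
            wsz = sizes[wild]
            if any(
                abs(wsz - sizes[a]) < c.min_gap
                for a in list(cultivars) + ["__ref__"]
            ):
                continue
            key = (devsum, -(f.gc3 + r.gc3), ref_size, f.start, r.start)
            ranked.append((key, f, r, sizes))
            ranked.sort(key=lambda t: t[0])
            if len(ranked) > n_candidates:
                ranked.pop()
            if len(ranked) >= n_candidates:
                worst = ranked[-1][0][0]

    markers = []
    for key, f, r, sizes in ranked:
        expected = {a: sizes[a] for a in msa.rows}
        ref_acc_size = sizes["__ref__"]
        fwd_primer = Primer(
            f.seq, bait.start + f.start, "+", len(f.seq),
            round(gc_fraction(f.seq), 4), round(f.tm, 2),
        )
        rev_primer = Primer(
            r.seq, bait.start + r.start, "-", len(r.seq),
            round(gc_fraction(r.seq), 4), round(r.tm, 2),
        )
        expected["__ref__"] = ref_acc_size
        markers.append(
            Marker(
                "", bait.chrom, bait.start + site.ref_start,
                fwd_primer, rev_primer, expected, site,
            )
        )
    return markers


def check_uniqueness(primer: str | Primer, reference: dict[str, str]) -> int:
    """Exact occurrences of the primer and its reverse complement across the
    reference (both strands)."""
    seq = primer.sequence if isinstance(primer, Primer) else primer
    rc = revcomp(seq)
    hits = 0
    for chrom_seq in reference.values():
        hits += count_occurrences(chrom_seq, seq)
        hits += count_occurrences(chrom_seq, rc)
    return hits


def name_marker(genome_code: str, chromosome: int, position: int) -> str:
    """CxxPxxxxx name: genome code, 2-digit chromosome, 5-digit kb position."""
    if not genome_code:
        raise ValueError("genome code required")
    if not (1 <= chromosome <= 99):
        raise ValueError(f"chromosome {chromosome} out of range 1..99")
    if position < 0:
        raise ValueError("negative position")
    if position >= 10 ** 8:
        raise ValueError("position overflows the 5-digit kb field")
    return f"{genome_code}{chromosome:02d}P{position // 1000:05d}"


def parse_chromosome_number(chrom: str) -> int:
    m = re.search(r"(\d+)$", chrom)
    if not m:
        raise ValueError(f"cannot parse chromosome number from {chrom!r}")
    return int(m.group(1))


def select_spaced_markers(
    candidates: list[Marker], interval: int = 2_000_000
) -> list[Marker]:
    """Greedy ~interval spacing per chromosome from coordinate 0: pick the
    candidate nearest each successive anchor (within +/- interval/2); after a
    pick the next anchor advances by ``interval`` from the picked marker."""
    by_chrom: dict[str, list[Marker]] = {}
    for mk in candidates:
        by_chrom.setdefault(mk.chrom, []).append(mk)
    selected: list[Marker] = []
    half = interval / 2
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda m: m.position)
        used = [False] * len(cands)
        anchor = 0
        max_pos = cands[-1].position
        while anchor <= max_pos + half:
            best_i = None
            for i, mk in enumerate(cands):
                if used[i] or abs(mk.position - anchor) > half:
                    continue
                if best_i is None or abs(mk.position - anchor) < abs(
                    cands[best_i].position - anchor
                ):
                    best_i = i
            if best_i is not None:
                used[best_i] = True
                selected.append(cands[best_i])
                anchor = cands[best_i].position + interval
            else:
                anchor += interval
    return selected


def audit_marker(
    marker: Marker,
    reference: dict[str, str],
    wild: str,
    cultivars: list[str],
    constraints: PrimerConstraints | None = None,
) -> list[str]:
    """Mechanical re-check of every printed design constraint; returns a list
    of violations (empty = marker passes)."""
    c = constraints or PrimerConstraints()
    bad = []
    for tag, p in (("fwd", marker.forward), ("rev", marker.reverse)):
        if not (c.min_length <= p.length <= c.max_length):
            bad.append(f"{tag} length {p.length}")
        g = gc_fraction(p.sequence)
        if not (c.gc_range[0] <= g <= c.gc_range[1]):
            bad.append(f"{tag} GC {g:.2f}")
        t = melting_temperature(p.sequence)
        if not (c.tm_range[0] <= t <= c.tm_range[1]):
            bad.append(f"{tag} Tm {t:.1f}")
        if _max_mono_run(p.sequence) > c.max_mono_run:
            bad.append(f"{tag} mononucleotide run")
        if check_uniqueness(p.sequence, reference) != 1:
            bad.append(f"{tag} not unique in reference")
    if abs(melting_temperature(marker.forward.sequence)
           - melting_temperature(marker.reverse.sequence)) > c.max_tm_difference:
        bad.append("Tm difference")
    wsz = marker.expected_size[wild]
    for acc in cultivars + ["__ref__"]:
        sz = marker.expected_size[acc]
        if not (c.product_range[0] <= sz <= c.product_range[1]):
            bad.append(f"{acc} product {sz}")
        if abs(wsz - sz) < c.min_gap:
            bad.append(f"wild-{acc} size gap {abs(wsz - sz)}")
    if not re.fullmatch(r"[A-Z]+\d{2}P\d{5}", marker.name or ""):
        bad.append(f"name {marker.name!r}")
    return bad
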