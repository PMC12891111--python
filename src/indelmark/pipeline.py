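"""End-to-end marker design: tile -> anchor -> chain -> align -> screen ->
design -> uniqueness -> name, with per-stage attrition accounting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .alignment import AlignmentError, align_pair, project_to_reference
from .io import RunConfig
from .markers import (
    Marker,
    PrimerConstraints,
    call_indels,
    check_uniqueness,
    design_primer_pair,
    name_marker,
    parse_chromosome_number,
    screen_indels,
    select_spaced_markers,
)
from .orthologs import extract_ortholog, find_anchors_batch
from .simulate import CULTIVAR, WILD, GenomePanel, PlantedIndel, TruthSet
from .tiling import Bait, RepeatTrack, tile_baits

logger = logging.getLogger(__name__)

GENOME_CODE = "C"  # markers target a CC-genome wild relative


@dataclass
class DesignResult:
    baits: list[Bait]
    markers: list[Marker]
    ortholog_status: dict[tuple[str, str], str]  # (bait_id, accession) -> status
    attrition: dict[str, int] = field(default_factory=dict)

    def attrition_report(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.attrition.items())


def design_markers(
    panel: GenomePanel,
    repeats: RepeatTrack,
    config: RunConfig | None = None,
    constraints: PrimerConstraints | None = None,
) -> DesignResult:
    """Run the full design funnel on a genome panel.

    Baits failing ortholog detection in any cultivar or the wild genome are
    dropped (only loci shared across the whole panel are usable); screened
    sites yield the best-ranked primer pair whose two primers are unique in
    the reference.
    """
    cfg = config or RunConfig()
    cons = constraints or PrimerConstraints(min_gap=cfg.min_gap)
    ref = panel.reference
    ref_genome = {c: s[0] for c, s in ref.haplotypes.items()}
    cultivars = panel.members(CULTIVAR)
    wilds = panel.members(WILD)
    if len(wilds) != 1:
        raise ValueError("design requires exactly one wild genome in the panel")
    wild = wilds[0]
    targets = cultivars + [wild]

    att = {
        "baits_tiled": 0,
        "baits_dropped_no_ortholog": 0,
        "baits_dropped_alignment": 0,
        "baits_aligned": 0,
        "sites_called": 0,
        "sites_screened": 0,
        "sites_dropped_no_primer": 0,
        "sites_dropped_uniqueness": 0,
        "markers_emitted": 0,
    }

    baits = tile_baits(
        ref_genome,
        repeats,
        interval=cfg.interval,
        bait_length=cfg.bait_length,
        max_repeat_fraction=cfg.max_repeat_fraction,
        shift_limit=cfg.shift_limit,
    )
    att["baits_tiled"] = len(baits)

    anchors_by_target = {
        acc.name: find_anchors_batch(
            baits, {c: s[0] for c, s in acc.haplotypes.items()}, cfg.word_size
        )
        for acc in targets
    }

    status: dict[tuple[str, str], str] = {}
    markers: list[Marker] = []
    for bait in baits:
        regions = {}
        ok = True
        for acc in targets:
            genome = {c: s[0] for c, s in acc.haplotypes.items()}
            region = extract_ortholog(
                bait,
                genome,
                word_size=cfg.word_size,
                uniqueness_ratio=cfg.uniqueness_ratio,
                margin=cfg.margin,
                min_coverage=cfg.min_coverage,
                max_gap_ratio=cfg.max_gap_ratio,
                accession=acc.name,
                anchors=anchors_by_target[acc.name][bait.bait_id],
            )
            if region is None:
                status[(bait.bait_id, acc.name)] = "absent"
                ok = False
            else:
                status[(bait.bait_id, acc.name)] = region.status
                regions[acc.name] = (region, genome)
        if not ok:
            att["baits_dropped_no_ortholog"] += 1
            continue

        try:
            pairwise = [
                align_pair(bait, region, genome)
                for region, genome in regions.values()
            ]
        except AlignmentError as exc:
            logger.warning("%s", exc)
            att["baits_dropped_alignment"] += 1
            continue
        msa = project_to_reference(bait, pairwise)
        att["baits_aligned"] += 1

        cult_names = [a.name for a in cultivars]
        sites = call_indels(msa, wild.name, cult_names)
        att["sites_called"] += len(sites)
        screened = screen_indels(sites, cfg.min_gap)
        att["sites_screened"] += len(screened)

        chrom_no = parse_chromosome_number(bait.chrom)
        for site in screened:
            candidates = design_primer_pair(
                msa, site, wild.name, cult_names, cons, n_candidates=5
            )
            if not candidates:
                att["sites_dropped_no_primer"] += 1
                continue
            chosen = None
            for cand in candidates:
                # primers repeated within the bait itself (tandem tracts)
                # cannot be genome-unique; skip the whole-genome scan
                if any(
                    check_uniqueness(p, {"bait": bait.sequence}) > 1
                    for p in (cand.forward.sequence, cand.reverse.sequence)
                ):
                    continue
                fh = check_uniqueness(cand.forward.sequence, ref_genome)
                rh = check_uniqueness(cand.reverse.sequence, ref_genome)
                if fh == 1 and rh == 1:
                    cand.forward = replace(cand.forward, genome_hit_count=fh)
                    cand.reverse = replace(cand.reverse, genome_hit_count=rh)
                    chosen = cand
                    break
            if chosen is None:
                att["sites_dropped_uniqueness"] += 1
                logger.info(
                    "site %s:%d dropped: no unique primer pair",
                    site.bait_id, site.ref_start,
                )
                continue
            chosen.name = name_marker(GENOME_CODE, chrom_no, chosen.position)
            chosen.expected_size[ref.name] = chosen.expected_size["__ref__"]
            markers.append(chosen)
            att["markers_emitted"] += 1

    markers.sort(key=lambda m: (m.chrom, m.position))
    return DesignResult(baits, markers, status, att)


def thin_markers(result: DesignResult, interval: int) -> list[Marker]:
    """Apply ~interval spacing selection to an emitted marker set."""
    return select_spaced_markers(result.markers, interval)


# ---------------------------------------------------------------------------
# Ground-truth evaluation (synthetic panels)

DESIGN_CONTEXT = 250  # bp of bait interior a site needs for flanks + primers


def eligible_planted_indels(
    truth: TruthSet, baits: list[Bait], context: int = DESIGN_CONTEXT
) -> list[PlantedIndel]:
    """Planted InDels whose design context (site +/- ``context`` bp, covering
    the reserved conserved flanks and primer windows) lies inside a tiled
    bait — the denominator for recovery statistics."""
    out = []
    for ev in truth.planted_indels:
        s, e = ev.ref_span
        for bait in baits:
            if bait.chrom == ev.chrom and bait.start <= s - context and e + context <= bait.end:
                out.append(ev)
                break
    return out


def recovered_planted_indels(
    truth: TruthSet,
    baits: list[Bait],
    markers: list[Marker],
    context: int = DESIGN_CONTEXT,
    slack: int = 10,
) -> tuple[list[PlantedIndel], list[PlantedIndel]]:
    """(eligible, recovered): eligible planted events and the subset with an
    emitted marker whose InDel site overlaps the event (+/- ``slack`` bp for
    alignment-equivalent gap placement)."""
    eligible = eligible_planted_indels(truth, baits, context)
    bait_by_id = {b.bait_id: b for b in baits}
    recovered = []
    for ev in eligible:
        s, e = ev.ref_span
        hit = False
        for mk in markers:
            bait = bait_by_id[mk.indel_site.bait_id]
            if bait.chrom != ev.chrom:
                continue
            m0 = bait.start + mk.indel_site.ref_start
            m1 = bait.start + mk.indel_site.ref_end
            if m0 - slack <= e and s <= m1 + slack:
                hit = True
                break
        if hit:
            recovered.append(ev)
    return eligible, recovered
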