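"""Synthetic multi-genome panels with known InDel ground truth.

The generator emulates the divergence structure the marker-design pipeline
assumes: a 12-chromosome reference (cultivated-rice-like, AA genome), extra
cultivars at low divergence from the reference, and one wild genome
(CC-genome-like) at high divergence that additionally carries *planted*
InDels of at least 20 bp — the events the pipeline is supposed to turn into
agarose-resolvable markers.  Every planted InDel keeps a 200-bp
mutation-free window on both sides in every genome, so a conserved primer
flank always exists, and is recorded in a :class:`TruthSet` together with
repeat tracts and (for derived accessions) introgression segments.

Derived accessions model the downstream validation materials: primer-site
knockouts (no-amplification controls), BC1F1 introgression mosaics, F1
hybrids, and allotetraploid-like genomes that carry the wild subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import random_dna, revcomp

FLANK_RESERVE = 200  # bp kept mutation-free on each side of a planted InDel

REFERENCE = "reference"
CULTIVAR = "cultivar"
WILD = "wild"
DERIVED = "derived"


@dataclass(frozen=True)
class Mutation:
    """One edit relative to the reference: replaces ``ref_len`` bases at
    ``pos`` (0-based reference coordinate) with ``alt``.

    SNP: ref_len=1, len(alt)=1.  Deletion: alt="".  Insertion: ref_len=0
    (alt inserted *before* ``pos``).
    """

    pos: int
    ref_len: int
    alt: str

    @property
    def length_change(self) -> int:
        return len(self.alt) - self.ref_len


@dataclass(frozen=True)
class PlantedIndel:
    chrom: str
    pos: int          # 0-based reference coordinate of the event
    length: int       # bp
    kind: str         # insertion_in_wild | deletion_in_wild

    @property
    def ref_span(self) -> tuple[int, int]:
        """Reference interval occupied by the event (empty for insertions)."""
        if self.kind == "deletion_in_wild":
            return (self.pos, self.pos + self.length)
        return (self.pos, self.pos)


@dataclass
class TruthSet:
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    repeat_tracts: list[tuple[str, int, int]] = field(default_factory=list)
    introgression_segments: dict[str, list[tuple[str, int, int, str]]] = field(
        default_factory=dict
    )


@dataclass
class Accession:
    name: str
    role: str
    species: str
    # chrom -> tuple of haplotype sequences (length 1, or 2 for F1/tetraploid)
    haplotypes: dict[str, tuple[str, ...]]
    # chrom -> sorted non-overlapping mutation list vs the reference, when the
    # genome is a single-haplotype edit of the reference; None otherwise
    mutations: dict[str, list[Mutation]] | None = None

    def sequence(self, chrom: str) -> str:
        """Single-haplotype sequence (errors for heterozygous accessions)."""
        haps = self.haplotypes[chrom]
        if len(haps) != 1:
            raise ValueError(f"{self.name} is not single-haplotype on {chrom}")
        return haps[0]

    @property
    def is_heterozygous(self) -> bool:
        return any(len(h) > 1 for h in self.haplotypes.values())


@dataclass
class GenomePanel:
    accessions: dict[str, Accession]

    @property
    def reference(self) -> Accession:
        refs = [a for a in self.accessions.values() if a.role == REFERENCE]
        if len(refs) != 1:
            raise ValueError("panel must contain exactly one reference")
        return refs[0]

    def members(self, *roles: str) -> list[Accession]:
        return [a for a in self.accessions.values() if a.role in roles]

    def add(self, acc: Accession) -> None:
        if acc.name in self.accessions:
            raise ValueError(f"duplicate accession id {acc.name!r}")
        self.accessions[acc.name] = acc

    def chromosomes(self) -> list[str]:
        return list(self.reference.haplotypes)

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: len(s[0]) for c, s in self.reference.haplotypes.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Rates are per-bp event probabilities.  The wild genome models a
    high-divergence relative (conserved orthologous regions of a different
    *Oryza* genome type); cultivars model within-species divergence from the
    reference cultivar.
    """

    n_chromosomes: int = 12
    chromosome_length: int = 2_000_000
    n_cultivars: int = 2
    cultivar_snp_rate: float = 0.005
    cultivar_small_indel_rate: float = 5e-4
    wild_snp_rate: float = 0.02
    wild_indel_rate: float = 2e-3
    planted_indel_spacing: int = 200_000
    planted_indel_length_range: tuple[int, int] = (20, 60)
    repeat_fraction: float = 0.05
    repeat_tract_length: int = 2_000
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "cultivar_snp_rate",
            "cultivar_small_indel_rate",
            "wild_snp_rate",
            "wild_indel_rate",
            "repeat_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        lo, hi = self.planted_indel_length_range
        if lo < 20:
            raise ValueError("planted InDels must be at least 20 bp")
        if hi < lo:
            raise ValueError("invalid planted_indel_length_range")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        # each planted event needs its clean flanks plus breathing room
        if self.planted_indel_spacing < 2 * (2 * FLANK_RESERVE + hi + 50) + 100:
            raise ValueError(
                "planted_indel_spacing too small for the reserved "
                f"{FLANK_RESERVE}-bp clean flanks"
            )
        if self.repeat_tract_length < 50:
            raise ValueError("repeat_tract_length must be >= 50 (one unit)")


def chromosome_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def apply_mutations(ref: str, mutations: list[Mutation]) -> str:
    """Apply a sorted, non-overlapping mutation list to a reference string."""
    pieces: list[str] = []
    cur = 0
    for m in mutations:
        if m.pos < cur:
            raise ValueError("mutations overlap or are unsorted")
        pieces.append(ref[cur:m.pos])
        pieces.append(m.alt)
        cur = m.pos + m.ref_len
    pieces.append(ref[cur:])
    return "".join(pieces)


def mutated_slice(ref: str, mutations: list[Mutation], start: int, end: int) -> str:
    """Sequence of ``ref[start:end]`` after applying the mutations that fall
    entirely inside the interval (boundary-crossing edits are dropped)."""
    inside = [
        m for m in mutations
        if m.pos >= start and m.pos + m.ref_len <= end
        and not (m.ref_len == 0 and m.pos == start)  # insertion at left edge
    ]
    shifted = [replace(m, pos=m.pos - start) for m in inside]
    return apply_mutations(ref[start:end], shifted)


def _place_repeat_tracts(
    rng: np.random.Generator, length: int, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    tract_len = cfg.repeat_tract_length
    n = int(cfg.repeat_fraction * length / tract_len)
    if n == 0:
        return []
    block = length // n
    if block <= tract_len:
        raise ValueError("repeat_fraction/repeat_tract_length leave no room")
    tracts = []
    for k in range(n):
        off = int(rng.integers(0, block - tract_len))
        start = k * block + off
        tracts.append((start, start + tract_len))
    return tracts


def _plant_indels(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    tracts: list[tuple[int, int]],
    cfg: SimulationConfig,
    next_is_insertion: bool,
) -> tuple[list[PlantedIndel], bool]:
    lo, hi = cfg.planted_indel_length_range
    spacing = cfg.planted_indel_spacing
    events: list[PlantedIndel] = []
    last_end = -(10 ** 9)
    n_slots = length // spacing
    slot_margin = 2 * FLANK_RESERVE + hi + 50
    for k in range(n_slots):
        placed = None
        for _ in range(20):  # re-draw if the slot position lands badly
            # uniform within the slot: consecutive events ~spacing apart on
            # average but unsynchronised with any downstream tiling grid
            pos = k * spacing + int(
                rng.integers(slot_margin, spacing - slot_margin)
            )
            ell = int(rng.integers(lo, hi + 1))
            ref_len = ell if not next_is_insertion else 0
            w0, w1 = pos - FLANK_RESERVE, pos + ref_len + FLANK_RESERVE
            if w0 < 0 or w1 > length:
                continue
            if w0 <= last_end:
                continue
            if any(t0 < w1 and w0 < t1 for t0, t1 in tracts):
                continue
            placed = PlantedIndel(
                chrom,
                pos,
                ell,
                "insertion_in_wild" if next_is_insertion else "deletion_in_wild",
            )
            last_end = w1
            break
        if placed is not None:
            events.append(placed)
            next_is_insertion = not next_is_insertion
    return events, next_is_insertion


def _draw_mutations(
    rng: np.random.Generator,
    ref: str,
    snp_rate: float,
    indel_rate: float,
    forbidden: np.ndarray,
    max_indel: int = 10,
    planted: list[Mutation] | None = None,
) -> list[Mutation]:
    """SNPs and small indels outside forbidden positions, merged with any
    pre-placed (planted) events; sorted and non-overlapping."""
    L = len(ref)
    occupied = forbidden.copy()
    muts: list[Mutation] = []
    if planted:
        for m in planted:
            muts.append(m)
            occupied[max(0, m.pos - 1): m.pos + m.ref_len + 1] = True

    if indel_rate > 0:
        pos_arr = np.nonzero(rng.random(L) < indel_rate)[0]
        lens = rng.integers(1, max_indel + 1, len(pos_arr))
        kinds = rng.random(len(pos_arr)) < 0.5  # True = insertion
        for p, ell, ins in zip(pos_arr.tolist(), lens.tolist(), kinds.tolist()):
            ref_len = 0 if ins else ell
            if p + ref_len >= L:
                continue
            if occupied[p: p + max(ref_len, 1)].any():
                continue
            alt = random_dna(rng, ell) if ins else ""
            muts.append(Mutation(p, ref_len, alt))
            occupied[max(0, p - 1): p + max(ref_len, 1) + 1] = True

    if snp_rate > 0:
        pos_arr = np.nonzero(rng.random(L) < snp_rate)[0]
        ok = ~occupied[pos_arr]
        ref_bytes = np.frombuffer(ref.encode(), dtype=np.uint8)
        for p in pos_arr[ok].tolist():
            base = chr(ref_bytes[p])
            alts = [b for b in "ACGT" if b != base]
            muts.append(Mutation(p, 1, alts[int(rng.integers(0, 3))]))

    muts.sort(key=lambda m: (m.pos, m.ref_len))
    return muts


def simulate_panel(config: SimulationConfig) -> tuple[GenomePanel, TruthSet]:
    """Generate a reference, ``n_cultivars`` cultivars and one wild genome.

    Deterministic for a given config (identical seed => byte-identical
    panel).  The wild genome carries all planted InDels; every planted event
    has a 200-bp mutation-free flank on each side in every genome.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    truth = TruthSet()

    ref_seqs: dict[str, str] = {}
    tracts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    planted_by_chrom: dict[str, list[PlantedIndel]] = {}
    next_ins = True
    for i in range(config.n_chromosomes):
        chrom = chromosome_name(i)
        L = config.chromosome_length
        seq = bytearray(random_dna(rng, L), "ascii")
        tracts = _place_repeat_tracts(rng, L, config)
        for t0, t1 in tracts:
            unit = random_dna(rng, 50)
            copies = (unit * ((t1 - t0) // 50 + 1))[: t1 - t0]
            seq[t0:t1] = copies.encode()
        ref_seqs[chrom] = seq.decode()
        tracts_by_chrom[chrom] = tracts
        truth.repeat_tracts.extend((chrom, t0, t1) for t0, t1 in tracts)
        events, next_ins = _plant_indels(rng, chrom, L, tracts, config, next_ins)
        planted_by_chrom[chrom] = events
        truth.planted_indels.extend(events)

    # forbidden (mutation-free) mask per chromosome: planted flanks + event
    forbidden: dict[str, np.ndarray] = {}
    for chrom, seq in ref_seqs.items():
        mask = np.zeros(len(seq), dtype=bool)
        for ev in planted_by_chrom[chrom]:
            s, e = ev.ref_span
            mask[max(0, s - FLANK_RESERVE): e + FLANK_RESERVE] = True
        forbidden[chrom] = mask

    panel = GenomePanel({})
    panel.add(
        Accession(
            "REF",
            REFERENCE,
            "O. sativa (reference cultivar)",
            {c: (s,) for c, s in ref_seqs.items()},
            mutations={c: [] for c in ref_seqs},
        )
    )

    for j in range(config.n_cultivars):
        muts = {
            chrom: _draw_mutations(
                rng,
                ref_seqs[chrom],
                config.cultivar_snp_rate,
                config.cultivar_small_indel_rate,
                forbidden[chrom],
            )
            for chrom in ref_seqs
        }
        panel.add(
            Accession(
                f"CULT{j + 1:02d}",
                CULTIVAR,
                "O. sativa",
                {c: (apply_mutations(ref_seqs[c], m),) for c, m in muts.items()},
                mutations=muts,
            )
        )

    wild_muts: dict[str, list[Mutation]] = {}
    for chrom in ref_seqs:
        planted_mut = []
        for ev in planted_by_chrom[chrom]:
            if ev.kind == "deletion_in_wild":
                planted_mut.append(Mutation(ev.pos, ev.length, ""))
            else:
                planted_mut.append(Mutation(ev.pos, 0, random_dna(rng, ev.length)))
        wild_muts[chrom] = _draw_mutations(
            rng,
            ref_seqs[chrom],
            config.wild_snp_rate,
            config.wild_indel_rate,
            forbidden[chrom],
            planted=planted_mut,
        )
    panel.add(
        Accession(
            "WILD",
            WILD,
            "CC-genome wild species",
            {c: (apply_mutations(ref_seqs[c], m),) for c, m in wild_muts.items()},
            mutations=wild_muts,
        )
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Derived accessions


@dataclass(frozen=True)
class DerivationSpec:
    """Description of a derived accession.

    kind: primer_site_knockout | bc1f1_mosaic | f1_heterozygote |
    tetraploid_union.  ``segments`` (bc1f1) are reference-coordinate
    (chrom, start, end) donor intervals; ``window`` (knockout) is a
    (chrom, start, end) interval in the *target's own* coordinates.
    """

    name: str
    kind: str
    recipient: str = ""
    donor: str = ""
    segments: tuple[tuple[str, int, int], ...] = ()
    window: tuple[str, int, int] | None = None
    species: str = "derived"


def _scramble(seq: str) -> str:
    # complement without reversing: no primer (either strand) survives
    return revcomp(seq)[::-1]


def derive_accession(
    panel: GenomePanel, spec: DerivationSpec, truth: TruthSet | None = None
) -> GenomePanel:
    """Add a derived accession to the panel (returned for chaining)."""
    if spec.kind == "primer_site_knockout":
        target = panel.accessions[spec.recipient]
        if spec.window is None:
            raise ValueError("primer_site_knockout requires a window")
        chrom, w0, w1 = spec.window
        haps = dict(target.haplotypes)
        seq = target.sequence(chrom)
        if not (0 <= w0 < w1 <= len(seq)):
            raise ValueError("knockout window out of bounds")
        haps[chrom] = (seq[:w0] + _scramble(seq[w0:w1]) + seq[w1:],)
        panel.add(Accession(spec.name, DERIVED, spec.species, haps))
        return panel

    if spec.kind == "bc1f1_mosaic":
        recipient = panel.accessions[spec.recipient]
        donor = panel.accessions[spec.donor]
        if recipient.mutations is None or donor.mutations is None:
            raise ValueError("mosaic parents must be reference-derived genomes")
        ref = panel.reference
        haps: dict[str, tuple[str, ...]] = {}
        muts: dict[str, list[Mutation]] = {}
        seg_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s0, s1 in spec.segments:
            if chrom not in ref.haplotypes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not (0 <= s0 < s1 <= len(ref.sequence(chrom))):
                raise ValueError("introgression segment out of bounds")
            seg_by_chrom.setdefault(chrom, []).append((s0, s1))
        for chrom in ref.haplotypes:
            segs = sorted(seg_by_chrom.get(chrom, []))
            inside = lambda m: any(
                s0 <= m.pos and m.pos + m.ref_len <= s1 for s0, s1 in segs
            )
            merged = [m for m in recipient.mutations[chrom] if not inside(m)]
            merged += [m for m in donor.mutations[chrom] if inside(m)]
            merged.sort(key=lambda m: (m.pos, m.ref_len))
            muts[chrom] = merged
            haps[chrom] = (apply_mutations(ref.sequence(chrom), merged),)
        panel.add(
            Accession(spec.name, DERIVED, spec.species, haps, mutations=muts)
        )
        if truth is not None:
            truth.introgression_segments[spec.name] = [
                (c, s0, s1, spec.donor) for c, s0, s1 in spec.segments
            ]
        return panel

    if spec.kind in ("f1_heterozygote", "tetraploid_union"):
        a = panel.accessions[spec.recipient]
        b = panel.accessions[spec.donor]
        haps = {}
        for chrom in a.haplotypes:
            if chrom not in b.haplotypes:
                raise ValueError(f"parents disagree on chromosome {chrom!r}")
            haps[chrom] = (a.sequence(chrom), b.sequence(chrom))
        panel.add(Accession(spec.name, DERIVED, spec.species, haps))
        return panel

    raise ValueError(f"unknown derivation kind {spec.kind!r}")
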