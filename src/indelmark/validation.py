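"""Virtual PCR, band matrices and the downstream marker analytics.

The band model is deliberately simple: a primer binds wherever its sequence
occurs exactly (optionally with mismatches, the 3'-terminal bases always
exact), and every convergent forward/reverse site pair within
``max_product`` bp yields a product.  Heterozygous accessions (F1 hybrids,
allotetraploid-like genomes) pool the products of both haplotypes, so a
codominant marker shows both parental bands.  Two bands are distinguishable
on a ~2% agarose gel when their sizes differ by at least ``min_resolvable``
bp (default 20, the same bound used at design time).

Downstream analytics mirror a wet-lab validation table: per-accession
polymorphic counts against each cultivar, no-amplification counts, the
overall polymorphic fraction, species-diagnostic marker discovery,
introgression/hybridity genotyping, and mean marker interval statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._seq import find_occurrences, revcomp
from .markers import Marker
from .simulate import Accession

logger = logging.getLogger(__name__)

MIN_RESOLVABLE = 20  # bp resolvable on ~2% agarose


@dataclass(frozen=True)
class BandResult:
    marker: str
    accession: str
    outcome: str  # single | multiple | none
    sizes: tuple[int, ...] = ()
    haplotype_sizes: tuple[tuple[int, ...], ...] = ()

    @property
    def size(self) -> int:
        if self.outcome != "single":
            raise ValueError(f"no unique band for {self.marker}/{self.accession}")
        return self.sizes[0]


def _binding_sites(
    primer: str, seq: str, max_mismatch: int, three_prime_exact: int
) -> tuple[list[int], list[int]]:
    """(plus-strand starts, minus-strand starts) of primer binding sites.

    A minus-strand site at q means the primer anneals to the reverse strand
    over seq[q : q + len); such sites terminate rightward products.
    """
    rc = revcomp(primer)
    if max_mismatch == 0:
        return find_occurrences(seq, primer), find_occurrences(seq, rc)
    k = len(primer)
    plus, minus = [], []
    for pat, out, tail_right in ((primer, plus, True), (rc, minus, False)):
        # 3' end of the annealed primer: right end on plus, left end on minus
        for i in range(len(seq) - k + 1):
            window = seq[i: i + k]
            if tail_right:
                if window[k - three_prime_exact:] != pat[k - three_prime_exact:]:
                    continue
            else:
                if window[:three_prime_exact] != pat[:three_prime_exact]:
                    continue
            mism = sum(1 for x, y in zip(window, pat) if x != y)
            if mism <= max_mismatch:
                out.append(i)
    return plus, minus


def virtual_pcr(
    marker: Marker,
    accession: Accession,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    max_product: int = 2_000,
) -> BandResult:
    """Expected band(s) of a marker on an accession (1 or 2 haplotypes)."""
    primers = (marker.forward.sequence, marker.reverse.sequence)
    hap_sizes: list[tuple[int, ...]] = []
    pooled: set[int] = set()
    n_haps = max(len(h) for h in accession.haplotypes.values())
    for hap_i in range(n_haps):
        sizes: set[int] = set()
        for chrom, haps in accession.haplotypes.items():
            if hap_i >= len(haps):
                continue
            seq = haps[hap_i]
            lefts: list[int] = []
            rights: list[tuple[int, int]] = []  # (start, primer length)
            for p in primers:
                plus, minus = _binding_sites(p, seq, max_mismatch, three_prime_exact)
                lefts.extend(plus)
                rights.extend((q, len(p)) for q in minus)
            for fp in lefts:
                for q, ln in rights:
                    size = q + ln - fp
                    if 0 < size <= max_product:
                        sizes.add(size)
        hap_sizes.append(tuple(sorted(sizes)))
        pooled.update(sizes)
    all_sizes = tuple(sorted(pooled))
    outcome = "none" if not all_sizes else "single" if len(all_sizes) == 1 else "multiple"
    return BandResult(marker.name, accession.name, outcome, all_sizes, tuple(hap_sizes))


def classify_pair(
    a: BandResult, b: BandResult, min_resolvable: int = MIN_RESOLVABLE
) -> str:
    """polymorphic | monomorphic | no_amp | ambiguous for one marker on two
    accessions.  Symmetric; absence of amplification is never counted as
    polymorphism."""
    if a.marker != b.marker:
        raise ValueError("band results belong to different markers")
    if a.outcome == "none" or b.outcome == "none":
        return "no_amp"
    if a.outcome == "multiple" or b.outcome == "multiple":
        return "ambiguous"
    return (
        "polymorphic"
        if abs(a.size - b.size) >= min_resolvable
        else "monomorphic"
    )


@dataclass
class BandMatrix:
    """Markers x accessions grid of band outcomes plus accession metadata."""

    results: dict[str, dict[str, BandResult]]  # marker -> accession -> band
    species: dict[str, str]
    roles: dict[str, str]

    @property
    def markers(self) -> list[str]:
        return list(self.results)

    @property
    def accessions(self) -> list[str]:
        return list(self.species)

    def band(self, marker: str, accession: str) -> BandResult:
        return self.results[marker][accession]


def build_band_matrix(
    markers: list[Marker],
    accessions: list[Accession],
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    max_product: int = 2_000,
) -> BandMatrix:
    results = {
        mk.name: {
            acc.name: virtual_pcr(mk, acc, max_mismatch, three_prime_exact, max_product)
            for acc in accessions
        }
        for mk in markers
    }
    return BandMatrix(
        results,
        {a.name: a.species for a in accessions},
        {a.name: a.role for a in accessions},
    )


def _round_half_up(x: float, digits: int) -> float:
    scale = 10 ** digits
    return int(x * scale + (0.5 if x >= 0 else -0.5)) / scale


@dataclass
class ValidationSummary:
    designed_count: int
    polymorphic_counts: dict[str, dict[str, int]]  # accession -> cultivar -> n
    no_amp_counts: dict[str, int]
    overall_polymorphic: int
    percentage: float
    mean_interval_mb: float | None = None


def summarize_matrix(
    matrix: BandMatrix,
    cultivar_ids: list[str],
    designed_count: int | None = None,
    min_resolvable: int = MIN_RESOLVABLE,
) -> ValidationSummary:
    """Per-accession polymorphism/no-amp tallies and the overall polymorphic
    count (markers polymorphic vs >= 1 cultivar in >= 1 non-cultivar
    accession)."""
    for c in cultivar_ids:
        if c not in matrix.species:
            raise ValueError(f"unknown cultivar id {c!r}")
    designed = designed_count if designed_count is not None else len(matrix.markers)
    others = [a for a in matrix.accessions if a not in cultivar_ids]
    poly: dict[str, dict[str, int]] = {a: {c: 0 for c in cultivar_ids} for a in others}
    no_amp = {a: 0 for a in others}
    overall = 0
    for mk in matrix.markers:
        any_poly = False
        for a in others:
            band = matrix.band(mk, a)
            if band.outcome == "none":
                no_amp[a] += 1
            for c in cultivar_ids:
                verdict = classify_pair(band, matrix.band(mk, c), min_resolvable)
                if verdict == "polymorphic":
                    poly[a][c] += 1
                    any_poly = True
        if any_poly:
            overall += 1
    pct = _round_half_up(overall / designed * 100.0, 1) if designed else 0.0
    return ValidationSummary(designed, poly, no_amp, overall, pct)


def summarize_counts_table(
    table: pd.DataFrame, designed_count: int = 182
) -> dict[str, object]:
    """Summary statistics from a per-accession validation count table
    (columns sample_code, species, genome, poly_vs_* and no_amp).

    The overall polymorphic count from count data is the maximum across the
    polymorphic-count columns (a full band matrix is needed for the exact
    union; with per-accession counts the maximum is the printable figure).
    """
    poly_cols = [c for c in table.columns if c.startswith("poly_vs_")]
    t = table.dropna(subset=poly_cols)
    out: dict[str, object] = {"designed_count": designed_count}
    for col in poly_cols:
        out[f"max_{col}"] = int(t[col].max())
        out[f"min_{col}"] = int(t[col].min())
    for genome, grp in t.groupby("genome"):
        for col in poly_cols:
            out[f"{genome}_max_{col}"] = int(grp[col].max())
            out[f"{genome}_min_{col}"] = int(grp[col].min())
    allpoly = t[poly_cols].to_numpy()
    overall = int(allpoly.max())
    out["overall_polymorphic"] = overall
    out["overall_percentage"] = _round_half_up(overall / designed_count * 100, 1)
    for genome, grp in t.groupby("genome"):
        vals = grp[poly_cols].to_numpy().ravel()
        out[f"{genome}_range"] = (int(vals.min()), int(vals.max()))
        out[f"{genome}_pct_range"] = (
            _round_half_up(vals.min() / designed_count * 100, 1),
            _round_half_up(vals.max() / designed_count * 100, 1),
        )
    return out


def _band_classes(
    values: list[tuple[str, str, tuple[int, ...]]], min_resolvable: int
) -> dict[str, object]:
    """Single-linkage size classes; accessions with no amplification get the
    'none' class, multi-band accessions an 'ambiguous' marker-specific one."""
    singles = [(acc, sizes[0]) for acc, out, sizes in values if out == "single"]
    singles.sort(key=lambda t: t[1])
    classes: dict[str, object] = {}
    cluster_id = 0
    prev_size = None
    for acc, size in singles:
        if prev_size is not None and size - prev_size >= min_resolvable:
            cluster_id += 1
        classes[acc] = cluster_id
        prev_size = size
    for acc, out, _ in values:
        if out == "none":
            classes[acc] = "none"
        elif out == "multiple":
            classes[acc] = f"ambiguous:{acc}"
    return classes


def find_species_specific(
    matrix: BandMatrix,
    species_of: dict[str, str] | None = None,
    min_resolvable: int = MIN_RESOLVABLE,
) -> list[tuple[str, str, str]]:
    """Markers whose band class is shared by all accessions of exactly one
    species and absent from every other wild accession.

    Returns (marker, species, class description) tuples in deterministic
    (marker, species) order.  A uniform no-amplification pattern may itself
    be diagnostic when every other species amplifies.
    """
    if species_of is None:
        species_of = {
            a: matrix.species[a]
            for a in matrix.accessions
            if matrix.roles.get(a) not in ("cultivar", "reference")
        }
    species = sorted(set(species_of.values()))
    if len(species) < 2:
        raise ValueError("need at least two species among wild accessions")
    hits = []
    for mk in matrix.markers:
        values = [
            (a, matrix.band(mk, a).outcome, matrix.band(mk, a).sizes)
            for a in species_of
        ]
        classes = _band_classes(values, min_resolvable)
        for sp in species:
            ins = [classes[a] for a in species_of if species_of[a] == sp]
            outs = [classes[a] for a in species_of if species_of[a] != sp]
            if len(set(ins)) != 1:
                continue
            cls = ins[0]
            if isinstance(cls, str) and cls.startswith("ambiguous"):
                continue
            if cls in outs:
                continue
            if cls == "none":
                desc = "no amplification"
            else:
                sz = sorted(
                    s[0]
                    for a, out, s in values
                    if species_of[a] == sp and out == "single"
                )
                desc = f"band ~{sz[0]} bp"
            hits.append((mk, sp, desc))
    return hits


@dataclass(frozen=True)
class GenotypeCall:
    marker: str
    accession: str
    call: str  # rice | wild | heterozygous | fail


def call_genotypes(
    band: BandResult,
    rice_band: int,
    wild_band: int,
    min_resolvable: int = MIN_RESOLVABLE,
) -> GenotypeCall:
    """Genotype a derived accession's band against the two parental bands."""
    if abs(rice_band - wild_band) < min_resolvable:
        raise ValueError(
            f"parental bands {rice_band}/{wild_band} are not resolvable"
        )
    tol = min_resolvable / 2
    has_rice = any(abs(s - rice_band) < tol for s in band.sizes)
    has_wild = any(abs(s - wild_band) < tol for s in band.sizes)
    if has_rice and has_wild:
        call = "heterozygous"
    elif has_rice:
        call = "rice"
    elif has_wild:
        call = "wild"
    else:
        call = "fail"
    return GenotypeCall(band.marker, band.accession, call)


def marker_interval_stats(
    markers: int | list[tuple[str, int]],
    chromosome_lengths: dict[str, int],
) -> dict[str, object]:
    """Mean marker interval in Mb (total genome length / marker count,
    2 decimals); with positions supplied, also the per-chromosome max gap."""
    total_mb = sum(chromosome_lengths.values()) / 1e6
    out: dict[str, object] = {}
    if isinstance(markers, int):
        count = markers
    else:
        count = len(markers)
        gaps: dict[str, float] = {}
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in markers:
            by_chrom.setdefault(chrom, []).append(pos)
        for chrom, L in chromosome_lengths.items():
            pts = sorted(by_chrom.get(chrom, []))
            bounds = [0] + pts + [L]
            gaps[chrom] = _round_half_up(
                max(b - a for a, b in zip(bounds, bounds[1:])) / 1e6, 2
            )
        out["max_gap_mb"] = gaps
    if count < 1:
        raise ValueError("at least one marker required")
    out["mean_interval_mb"] = _round_half_up(total_mb / count, 2)
    out["marker_count"] = count
    out["total_mb"] = round(total_mb, 6)
    return out
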