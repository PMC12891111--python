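"""Readers/writers for the standard formats, packaged data, run config and
the chromosome-map SVG renderer.

All user-facing coordinates in TSV/CSV outputs are 1-based inclusive;
internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .markers import Marker
from .tiling import RepeatTrack, merge_intervals


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {record id: uppercase sequence}.

    Errors on duplicate ids and empty files; N is accepted.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> RepeatTrack:
    """3+ column BED (0-based half-open) -> sorted, merged RepeatTrack."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            by_chrom.setdefault(chrom, []).append((start, end))
    return RepeatTrack({c: merge_intervals(v) for c, v in by_chrom.items()})


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Packaged reference data


def load_rice_chromosome_lengths() -> dict[str, int]:
    """IRGSP-1.0 chromosome lengths (bp), total 373,245,519."""
    text = resources.files("indelmark.data").joinpath(
        "irgsp1_chromosomes.tsv"
    ).read_text()
    out = {}
    for line in text.strip().splitlines()[1:]:
        chrom, length = line.split("\t")
        out[chrom] = int(length)
    return out


def load_validation_table() -> pd.DataFrame:
    """Packaged per-accession validation count table (182-marker panel)."""
    with resources.files("indelmark.data").joinpath(
        "table1_validation.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Marker tables


def markers_to_frame(markers: list[Marker], accession_order: list[str]) -> pd.DataFrame:
    rows = []
    for mk in markers:
        row = {
            "name": mk.name,
            "chrom": mk.chrom,
            "pos_1based": mk.position + 1,
            "fwd_seq": mk.forward.sequence,
            "rev_seq": mk.reverse.sequence,
            "fwd_tm": mk.forward.tm,
            "rev_tm": mk.reverse.tm,
            "fwd_gc": mk.forward.gc_fraction,
            "rev_gc": mk.reverse.gc_fraction,
        }
        for acc in accession_order:
            row[f"size_{acc}"] = mk.expected_size.get(acc, "")
        # the site's largest allele-length change (the wild allele, since
        # screened sites require cultivars to be reference-like)
        alleles = mk.indel_site.alleles
        row["indel_length"] = (
            max(alleles.values(), key=abs) if alleles else ""
        )
        row["status"] = "ok"
        rows.append(row)
    return pd.DataFrame(rows)


def write_marker_table(
    markers: list[Marker], accession_order: list[str], path: str | Path
) -> None:
    markers_to_frame(markers, accession_order).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chromosome map rendering


def render_marker_map(
    markers: list[tuple[str, int, str]],
    chromosome_lengths: dict[str, int],
    out_path: str | Path,
    width: int = 900,
    height: int = 500,
) -> str:
    """Deterministic SVG: one vertical bar per chromosome, one tick with the
    marker name per marker at its proportional position.

    ``markers`` are (chromosome, position bp, label) tuples.  Byte-identical
    output for identical input.
    """
    chroms = list(chromosome_lengths)
    if not chroms:
        raise ValueError("no chromosomes")
    for chrom, pos, label in markers:
        if chrom not in chromosome_lengths:
            raise ValueError(f"marker {label} on unknown chromosome {chrom!r}")
        if not (0 <= pos <= chromosome_lengths[chrom]):
            raise ValueError(f"marker {label} beyond end of {chrom}")
    max_len = max(chromosome_lengths.values())
    top, bottom = 40, 30
    usable = height - top - bottom
    slot = width / len(chroms)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="monospace" font-size="9">'
    ]
    for i, chrom in enumerate(chroms):
        x = slot * (i + 0.5)
        h = usable * chromosome_lengths[chrom] / max_len
        parts.append(
            f'<rect x="{x - 6:.1f}" y="{top}" width="12" height="{h:.1f}" '
            f'rx="6" fill="#dddddd" stroke="#555555"/>'
        )
        parts.append(
            f'<text x="{x:.1f}" y="{top - 8}" text-anchor="middle">{chrom}</text>'
        )
    for chrom, pos, label in sorted(markers):
        i = chroms.index(chrom)
        x = slot * (i + 0.5)
        y = top + usable * pos / max_len
        parts.append(
            f'<line class="marker-tick" x1="{x - 8:.1f}" y1="{y:.1f}" '
            f'x2="{x + 8:.1f}" y2="{y:.1f}" stroke="#cc0000"/>'
        )
        parts.append(
            f'<text x="{x + 10:.1f}" y="{y + 3:.1f}">{label}</text>'
        )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    Path(out_path).write_text(svg)
    return svg


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All pipeline tunables with their module defaults."""

    # inputs (panel FASTAs by accession or a simulation seed)
    panel_dir: str | None = None
    repeat_bed: str | None = None
    output_dir: str = "indelmark_run"
    rng_seed: int = 0
    log_level: str = "INFO"
    # simulation
    n_chromosomes: int = 12
    chromosome_length: int = 2_000_000
    n_cultivars: int = 2
    # bait tiling
    interval: int = 2_000_000
    bait_length: int = 20_000
    max_repeat_fraction: float = 0.2
    shift_limit: int = 500_000
    # ortholog search
    word_size: int = 80
    uniqueness_ratio: float = 0.5
    min_coverage: float = 0.1
    margin: int = 1_000
    max_gap_ratio: float = 0.25
    # screening / primer design
    min_gap: int = 20
    # virtual PCR
    max_mismatch: int = 0
    three_prime_exact: int = 3
    max_product: int = 2_000
    min_resolvable: int = 20

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        if str(path).endswith(".json"):
            Path(path).write_text(json.dumps(data, indent=2) + "\n")
        else:
            Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
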