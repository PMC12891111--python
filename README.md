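# indelmark

Genome-wide, agarose-resolvable InDel marker design for crosses between
cultivated rice (*Oryza sativa*, AA genome) and its distant wild relatives
(CC-genome species such as *O. officinalis*), plus the downstream analytics
used to validate such a marker set: virtual PCR band matrices, polymorphism
and no-amplification tallies, species-diagnostic marker discovery, and
introgression/hybridity genotyping.

## The problem

Markers built from *O. sativa* sequence alone (SSRs, STSs) often fail on
wild species outside the AA genome: primer sites diverge, bands are weak or
absent, and polymorphism is poor. The remedy is to design markers directly
from a comparison of the two genomes: find insertion/deletion differences of
at least 20 bp (cleanly separable on a ~2% agarose gel), and place both
primers on flanks conserved across every genome in the panel so the marker
amplifies in all of them. Scored on a gel, such markers are codominant — an
F1 hybrid shows both parental bands.

`indelmark` automates the whole funnel:

1. **Bait tiling** — ~20-kb windows of the reference every ~2 Mb per
   chromosome, walking from the short-arm tip and sliding windows in 1-kb
   steps to keep repeat content under a threshold.
2. **Ortholog search** — each bait is located in every other genome by
   maximal exact matches (word size ≥ 80 bp, both strands) chained
   colinearly; low coverage means the locus is absent or too diverged, and a
   strong second chain means paralogy — either way the bait is dropped.
3. **Alignment** — anchors are frozen and the sequence between them aligned
   with banded affine-gap dynamic programming (match +1, mismatch −1, gap
   open −4, extend −1); per-genome alignments are stacked on the reference.
4. **Marker design** — InDel sites where the wild allele differs from every
   cultivar by ≥ 20 bp (and the cultivars agree with the reference) get
   primer pairs from conserved flanks: length 18–25 nt, GC 0.40–0.60,
   Tm 50–60 °C (Tm = 64.9 + 41·(GC − 16.4)/N, target 55 °C), pair ΔTm ≤ 3 °C,
   cultivar products 100–500 bp, and both primers exactly unique in the
   reference. Markers are named `CxxPxxxxx` (genome code, chromosome,
   kb position).
5. **Validation** — exact-match virtual PCR produces a band matrix over any
   panel, from which polymorphism counts, species-diagnostic band classes and
   BC1F1/F1 genotype calls are derived.

Because chromosome-scale wild-rice assemblies are too large to ship, the
package includes a first-class synthetic panel generator
(`indelmark.simulate`) that emulates the AA/CC divergence structure with a
known truth set: planted ≥ 20-bp InDels with reserved conserved flanks,
tandem-repeat tracts, cultivar- and wild-level SNP/small-indel noise, and
derived accessions (F1 hybrids, BC1F1 introgression mosaics, primer-site
knockouts, allotetraploid-like genomes).

## Worked example

```python
from indelmark import (RepeatTrack, SimulationConfig, design_markers,
                       recovered_planted_indels, simulate_panel, virtual_pcr)
from indelmark.io import RunConfig

panel, truth = simulate_panel(SimulationConfig(rng_seed=1))  # 12 x 2 Mb
repeats = RepeatTrack.from_intervals(truth.repeat_tracts)
result = design_markers(panel, repeats, RunConfig(interval=200_000,
                                                  shift_limit=90_000))
print(result.attrition)
eligible, recovered = recovered_planted_indels(truth, result.baits,
                                               result.markers)
print(len(recovered), "of", len(eligible), "in-bait planted InDels recovered")
mk = result.markers[0]
print(mk.name, mk.expected_size)
```

prints (exact marker set depends on the seed):

```
{'baits_tiled': 120, 'baits_dropped_no_ortholog': 0,
 'baits_dropped_alignment': 0, 'baits_aligned': 120, 'sites_called': 7554,
 'sites_screened': 440, 'sites_dropped_no_primer': 99,
 'sites_dropped_uniqueness': 323, 'markers_emitted': 18}
18 of 18 in-bait planted InDels recovered
C01P00806 {'CULT01': 121, 'CULT02': 121, 'WILD': 177, '__ref__': 121, 'REF': 121}
```

Here 120 baits were tiled, every bait found a unique ortholog in both
cultivars and the wild genome, and each of the 18 planted InDels that fell
inside a bait (with room for its flanks) became a named marker. The
`expected_size` map gives the amplicon length per accession — the wild band
differs from every rice band by at least 20 bp, so the marker is scorable on
agarose. The large `sites_screened`/`sites_dropped_uniqueness` counts are
alignment-register artifacts inside tandem repeats; their candidate primers
are non-unique by construction, so the uniqueness screen removes all of them.

The same pipeline is exposed on the command line:

```bash
indelmark simulate --seed 1 --out panel/
indelmark design --panel-dir panel/ --out run/ --interval 200000
indelmark validate --panel-dir panel/ --markers run/markers.tsv --out val/
indelmark map --markers run/markers.tsv --out run/markers.svg
```

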