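# Methods

## Scope and model

`indelmark` designs PCR markers from length polymorphism: insertions or
deletions of at least 20 bp between a cultivated-rice reference (plus
additional cultivars) and a diverged wild genome, with both primers on
flanks conserved across the whole panel. The 20-bp bound plays two roles —
it is the design threshold (smaller length differences are not reliably
separable on a ~2% agarose gel) and, symmetrically, the resolvability bound
used when two bands are compared during validation. Both are exposed as
parameters (`min_gap`, `min_resolvable`) and default to 20 bp.

The pipeline is deliberately reference-pivoted. Every genome is compared to
the reference bait, never to the other genomes directly; the multiple
alignment is the stack of pairwise alignments keyed by reference position.
This matches how InDels-vs-reference are read off and keeps the construction
deterministic, at the cost of not aligning insertion content across
accessions (insertions at the same reference position are left-aligned and
padded; they are treated as independent events).

## Stage-by-stage choices

**Bait tiling.** Ideal anchors at 0, `interval`, 2·`interval`, … per
chromosome; coordinate 0 is treated as the short-arm tip (real assemblies
may orient arms differently — callers can reverse-complement before input if
that distinction matters). A window is acceptable when its repeat-annotation
overlap is ≤ `max_repeat_fraction` (default 0.2); unacceptable anchors shift
alternately ±1 kb up to `shift_limit`, ties toward the smaller coordinate,
and baits never overlap. The quantitative threshold replaces a manual
"avoid long repeats" inspection; 0.2 is a package decision, not an empirical
constant.

**Ortholog search.** Anchors are maximal exact matches of ≥ `word_size` bp
(default 80, within the 70–120 range such searches typically use), found by
hashing all bait k-mers (k = ⌈word_size/2⌉) and scanning the genome at
stride word_size − k + 1 — any match of the requested length necessarily
contains a stride-aligned seed, so the scheme is exact. Chaining maximizes
anchored bp over colinear anchors (strictly increasing starts and ends in
both coordinate systems). Anchors may overlap by a few bp — chance
extension past an InDel junction makes this routine — and an overlapped
successor contributes its length minus the larger coordinate overlap; chained
anchors are left-trimmed to disjointness before alignment. Positive gaps are
bounded by `max_gap_ratio` (default 0.25) times the bait length. A bait is
dropped in a genome when the chain covers < `min_coverage` (default 0.1) of
the bait (absence / high divergence) or when the best conflicting chain
scores > `uniqueness_ratio` (default 0.5) of the winner (paralogy,
duplication). Both thresholds are package decisions; marker design proceeds
only for baits with a unique ortholog in *every* cultivar and the wild
genome, since a common InDel call needs all of them.

**Alignment.** Gotoh three-state affine DP on the inter-anchor segments,
match +1 / mismatch −1 / gap open −4 / gap extend −1 (a gap of length L
costs −4 − (L−1)); `N` never matches. The band is the segment length
difference + 50; traceback tie order is diagonal, then vertical (gap in the
genome row), then horizontal, which makes alignments deterministic.
Segments longer than 50 kb abort the bait (logged) rather than risk an
unreliable giant alignment. Terminal gap runs of a row are alignment-edge
artifacts (the ortholog region is padded by `margin`, default 1 kb) and are
ignored by the InDel caller.

**InDel calling and screening.** Per accession, maximal gap/insertion runs
become events; events whose reference spans lie within 3 bp of one another
merge into one site (so a 2-bp island inside a 30-bp deletion does not split
it — the merge distance is a package decision). A site passes screening when
(a) the wild allele differs from every cultivar allele by ≥ `min_gap` and
(b) all cultivars are reference-like within ±3 bp — the common-InDel rule
that rejects variety-specific events.

**Primer design.** Candidate primers are 18–25-nt windows of conserved
blocks (columns where every accession carries the identical base, with no
insertion inside the window in any accession), within one maximum product
length of the site. Acceptance: GC ∈ [0.40, 0.60] and Tm ∈ [50, 60] °C —
operationalizing "about 50%" and "about 55 °C" — with Tm from the long-oligo
approximation Tm = 64.9 + 41·(G+C − 16.4)/N; no mononucleotide run ≥ 5;
pair ΔTm ≤ 3 °C; reference and cultivar products ∈ [100, 500] bp; wild
product ∈ [50, 2000] bp (an insertion allele may legitimately exceed 500 bp
— it only has to amplify); all wild-vs-rice size differences ≥ `min_gap`.
Pairs are ranked by |Tm_f − 55| + |Tm_r − 55|, ties preferring G/C 3' ends,
then the smaller product, then coordinates; the best pair whose two primers
are exactly unique in the reference (both strands counted) is emitted.
Uniqueness, not sequence context, is what removes the repeat-derived
candidate sites: tandem-repeat alignments can produce register-shift gap
calls, and all their primers collide with other repeat copies.

**Validation.** Virtual PCR binds primers at exact matches (a mismatch
budget with an always-exact 3' tail is available but defaults to 0) and
reports every convergent product ≤ 2 kb; heterozygous accessions pool both
haplotypes, so F1 hybrids show both parental bands (codominance). Two
singles differing ≥ `min_resolvable` are polymorphic; anything involving a
missing band is a no-amplification outcome, never polymorphism; multi-band
outcomes are ambiguous and excluded from the polymorphic counts.
Species-diagnostic markers use single-linkage band classes at the same
tolerance: a marker is diagnostic for a species when all its accessions
share one class absent from every other wild accession (a uniform
no-amplification pattern may itself be the diagnostic class). Genotype calls
match a band to a parent within half the resolvability bound; both parents
matched means heterozygous. Percentages round half-away-from-zero to one
decimal; mean marker interval is total genome length over marker count,
two decimals, using the packaged IRGSP-1.0 chromosome lengths
(total 373,245,519 bp).

One note on the packaged validation count table: it stores per-accession
polymorphic counts, not raw bands, so the "overall polymorphic" figure
derived from it is the maximum across its count columns; the exact union
over markers is only computable from a full band matrix, which
`summarize_matrix` provides for synthetic panels.

## The synthetic panel

The generator emulates what the analysis assumes about real panels, with a
truth set for every planted feature:

- **Reference**: 12 uniform-random chromosomes of 2 Mb (a ~1/15-scale rice
  genome; the tiling interval is scaled accordingly to 200 kb in the shipped
  end-to-end runs, preserving ~10 baits per chromosome).
- **Repeats**: exact tandem tracts of a random 50-bp unit, 2 kb long,
  covering 5% of the genome — enough to exercise repeat avoidance in tiling
  and the uniqueness screen, with no attempt at transposon realism.
- **Cultivars** (2): SNPs at 5×10⁻³/bp and 1–10-bp indels at 5×10⁻⁴/bp
  relative to the reference — within-species divergence.
- **Wild genome**: SNPs at 2×10⁻²/bp and small indels at 2×10⁻³/bp — a
  diverged genome whose *alignable* regions retain ~98% identity, which is
  the regime in which ortholog anchoring with an 80-bp word size is
  meaningful (regions more diverged than this would simply drop out, as some
  loci do in practice). No public AA↔CC divergence estimate fixes these
  rates; they are package defaults chosen once.
- **Planted InDels**: alternating insertions/deletions of 20–60 bp, one per
  ~200-kb slot at a uniform random position within the slot, each with a
  200-bp window on both sides kept free of *any* other mutation in *every*
  genome and clear of repeat tracts. The flank reservation is what makes
  "every in-bait planted InDel yields a marker" a testable property rather
  than a statistical tendency.
- **Derived accessions**: F1 heterozygotes and allotetraploid-like unions
  carry both parental haplotypes per chromosome; BC1F1 mosaics are recipient
  genomes with donor sequence swapped in over truth-recorded segments
  (single-haplotype mosaics — a modeling simplification; real BC1F1
  introgressions are heterozygous); primer-site knockouts complement a
  stated window so no primer binds on either strand.

What the panel does **not** emulate — and what passing tests therefore do
not show about real data: coalescent structure, transposon families and
nested repeats, heterozygosity outside derived accessions, assembly gaps and
Ns, sequencing error, PCR stochasticity and weak bands. Recovery statistics
on the synthetic panel demonstrate the machinery is correct, not that a real
AA/CC comparison would reach the same rates.

Recovery is reported over *eligible* planted InDels: those whose site ±250 bp
(the reserved flanks plus primer room) lies inside a tiled bait. An event
10 bp from a bait edge has no flank inside the alignment and cannot possibly
yield a marker; counting it would measure tiling coverage, not design
correctness.

## Numerical and degenerate-input notes

- Alignment scores are integers computed in float64; band width is capped so
  a pathological segment pair raises rather than allocates unboundedly.
- Empty-vs-nonempty alignment is a pure gap run; empty anchors chain to an
  empty region (score 0) and the bait is reported absent.
- `N` is accepted by all readers, uppercased, and treated as a universal
  mismatch; the simulator itself emits only ACGT.
- Marker names overflow above 10⁸ bp (five kb digits); chromosome numbers
  are restricted to 1–99.
- All user-facing tables are 1-based inclusive; everything internal is
  0-based half-open.
- Identical seed ⇒ byte-identical panels, marker tables and SVG maps.

## Problem sizes in the shipped runs

The end-to-end tests and the acceptance script run the default 24-Mb panel
(12 × 2 Mb, ~115 planted InDels, ~120 baits, 3 non-reference genomes);
oracle-equivalence checks run on instances small enough for exhaustive
enumeration (≤ 2-kb baits, ≤ 15 anchors, ≤ 500-bp alignments, 1-Mb
uniqueness scans). These sizes were chosen so the full suite exercises every
stage at genome-like structure while remaining a desk-scale computation.
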