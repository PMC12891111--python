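"""InDel screening, primer design rules, uniqueness and marker naming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark import (
    Bait,
    InDelSite,
    Marker,
    Primer,
    check_uniqueness,
    call_indels,
    gc_fraction,
    melting_temperature,
    name_marker,
    screen_indels,
    select_spaced_markers,
)
from indelmark.alignment import PairwiseAlignment, project_to_reference
from indelmark._seq import revcomp

from conftest import random_dna


def _msa(bait_seq, rows):
    """MSA from dict accession -> (gapped bait, gapped genome) pairs."""
    bait = Bait("b1", "chr01", 0, len(bait_seq), bait_seq, 0)
    pws = [PairwiseAlignment("b1", acc, ga, gg, 0) for acc, (ga, gg) in rows.items()]
    return project_to_reference(bait, pws)


class TestCallIndels:
    def test_single_gap_in_wild_row(self, rng):
        s = random_dna(rng, 200)
        ga = s
        gg = s[:100] + "-" * 25 + s[125:]
        msa = _msa(s, {"CULT01": (s, s), "WILD": (ga, gg)})
        sites = call_indels(msa, "WILD", ["CULT01"])
        assert len(sites) == 1
        site = sites[0]
        assert site.alleles["WILD"] == -25
        assert site.alleles["CULT01"] == 0
        assert site.event_type == "deletion_in_wild"
        assert site.wild_vs_all_cultivars_gap == 25
        assert site.cultivar_consistent

    def test_nearby_gaps_merge_into_one_site(self, rng):
        s = random_dna(rng, 200)
        gg = s[:50] + "-" * 15 + s[65:67] + "-" * 15 + s[82:]
        msa = _msa(s, {"CULT01": (s, s), "WILD": (s, gg)})
        sites = call_indels(msa, "WILD", ["CULT01"])
        assert len(sites) == 1
        assert sites[0].alleles["WILD"] == -30

    def test_distant_gaps_stay_separate(self, rng):
        s = random_dna(rng, 300)
        gg = s[:50] + "-" * 20 + s[70:150] + "-" * 20 + s[170:]
        msa = _msa(s, {"CULT01": (s, s), "WILD": (s, gg)})
        sites = call_indels(msa, "WILD", ["CULT01"])
        assert len(sites) == 2


class TestScreenIndels:
    def _site(self, wild, cult):
        gap = abs(wild - cult)
        return InDelSite(
            "b1", 100, 120, {"WILD": wild, "CULT01": cult},
            "deletion_in_wild" if wild < 0 else "insertion_in_wild",
            abs(cult) <= 3, gap,
        )

    def test_clean_25bp_wild_gap_kept(self):
        assert screen_indels([self._site(-25, 0)]) != []

    def test_below_threshold_rejected(self):
        assert screen_indels([self._site(-15, 0)]) == []

    def test_shared_indel_rejected_by_common_indel_rule(self):
        # wild and a cultivar both carry the 25-bp deletion
        assert screen_indels([self._site(-25, -25)]) == []


class TestPrimerArithmetic:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("AAAA", 0.0), ("GGGCCCAT", 0.75)],
    )
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == expected

    def test_gc_fraction_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError):
            gc_fraction("ACGN")

    def test_melting_temperature_formula(self):
        assert melting_temperature("GC" * 5 + "AT" * 5) == pytest.approx(51.78)
        assert melting_temperature("GC" * 6 + "AT" * 4) == pytest.approx(55.88)
        with pytest.raises(ValueError):
            melting_temperature("ACGTACGTACGECT"[:13])

    @given(st.text(alphabet="ACGT", min_size=14, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_tm_invariant_under_reverse_complement(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq))
        )


class TestUniqueness:
    def test_unique_and_tandem_copies(self, rng):
        core = random_dna(rng, 100)
        genome = {"chr01": random_dna(rng, 5_000) + core + random_dna(rng, 5_000)}
        primer = core[10:30]
        assert check_uniqueness(primer, genome) == 1
        triple = {"chr01": random_dna(rng, 1_000) + primer * 3 + random_dna(rng, 1_000)}
        assert check_uniqueness(primer, triple) == 3

    def test_reverse_complement_hits_counted(self, rng):
        primer = random_dna(rng, 22)
        genome = {"chr01": primer + random_dna(rng, 500) + revcomp(primer)}
        assert check_uniqueness(primer, genome) == 2

    @staticmethod
    def _naive_scan(hay, needle):
        """Position-by-position full scan (vectorised for speed)."""
        h = np.frombuffer(hay.encode(), np.uint8)
        k = len(needle)
        hit = np.ones(len(h) - k + 1, dtype=bool)
        for j, ch in enumerate(needle):
            hit &= h[j: len(h) - k + 1 + j] == ord(ch)
        return int(hit.sum())

    def test_counts_match_naive_scan_on_toy_genome(self, rng):
        genome_seq = random_dna(rng, 1_000_000)
        genome = {"chr01": genome_seq}
        rc_genome = revcomp(genome_seq)
        for _ in range(20):
            p0 = int(rng.integers(0, 10 ** 6 - 25))
            primer = genome_seq[p0: p0 + 20]
            naive = self._naive_scan(genome_seq, primer) + self._naive_scan(
                rc_genome, primer
            )
            assert check_uniqueness(primer, genome) == naive


class TestNaming:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            (4, 15_867_432, "C04P15867"),
            (7, 15_240_500, "C07P15240"),
            (10, 16_655_900, "C10P16655"),
            (7, 27_830_000, "C07P27830"),
            (8, 2_385_999, "C08P02385"),
            (1, 0, "C01P00000"),
        ],
    )
    def test_names_from_chromosome_and_kb_position(self, chrom, pos, expected):
        assert name_marker("C", chrom, pos) == expected

    def test_overflow_and_range_errors(self):
        with pytest.raises(ValueError):
            name_marker("C", 1, 10 ** 8)
        with pytest.raises(ValueError):
            name_marker("C", 0, 100)
        with pytest.raises(ValueError):
            name_marker("C", 100, 100)

    @given(st.integers(0, 10 ** 8 // 1000 - 1), st.integers(0, 10 ** 8 // 1000 - 1))
    @settings(max_examples=100, deadline=None)
    def test_injective_per_chromosome_at_kb_resolution(self, kb1, kb2):
        n1 = name_marker("C", 5, kb1 * 1000)
        n2 = name_marker("C", 5, kb2 * 1000)
        assert (n1 == n2) == (kb1 == kb2)


def _toy_marker(chrom, pos):
    p = Primer("ACGTACGTACGTACGTAC", pos, "+", 18, 0.5, 55.0)
    site = InDelSite("b", 0, 0, {}, "complex", True, 0)
    return Marker(f"M{pos}", chrom, pos, p, p, {}, site)


class TestSpacedSelection:
    def test_dense_candidates_thin_to_interval(self):
        cands = [_toy_marker("chr01", p) for p in range(0, 10_000_001, 500_000)]
        picked = select_spaced_markers(cands, interval=2_000_000)
        pos = [m.position for m in picked]
        assert pos[0] == 0
        assert all(1_000_000 <= b - a <= 3_000_000 for a, b in zip(pos, pos[1:]))
        assert 5 <= len(picked) <= 6

    def test_single_candidate_returned(self):
        cands = [_toy_marker("chr01", 1_234_567)]
        assert select_spaced_markers(cands) == cands

    @staticmethod
    def _oracle(positions, interval):
        half = interval / 2
        picked = []
        used = set()
        anchor = 0
        maxp = max(positions)
        while anchor <= maxp + half:
            best = None
            for i, p in enumerate(positions):
                if i in used or abs(p - anchor) > half:
                    continue
                if best is None or abs(p - anchor) < abs(positions[best] - anchor):
                    best = i
            if best is None:
                anchor += interval
            else:
                used.add(best)
                picked.append(positions[best])
                anchor = positions[best] + interval
        return picked

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nearest_to_anchor_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(
            int(p) for p in rng.integers(0, 20_000_000, int(rng.integers(3, 40)))
        )
        cands = [_toy_marker("chr01", p) for p in positions]
        picked = [m.position for m in select_spaced_markers(cands, 2_000_000)]
        assert picked == self._oracle(positions, 2_000_000)
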