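"""Virtual PCR, band classification, summary tallies, diagnostics,
genotyping and interval arithmetic."""

import numpy as np
import pytest

from indelmark import (
    BandMatrix,
    BandResult,
    call_genotypes,
    classify_pair,
    find_species_specific,
    marker_interval_stats,
    summarize_counts_table,
    summarize_matrix,
)
from indelmark.io import load_rice_chromosome_lengths, load_validation_table


def _band(marker, acc, *sizes):
    if not sizes:
        return BandResult(marker, acc, "none", ())
    out = "single" if len(sizes) == 1 else "multiple"
    return BandResult(marker, acc, out, tuple(sorted(sizes)))


class TestClassifyPair:
    def test_resolvable_difference_is_polymorphic(self):
        assert classify_pair(_band("m", "a", 180), _band("m", "b", 150)) == "polymorphic"

    def test_sub_resolution_difference_is_monomorphic(self):
        assert classify_pair(_band("m", "a", 180), _band("m", "b", 175)) == "monomorphic"

    def test_missing_band_is_no_amp_not_polymorphism(self):
        assert classify_pair(_band("m", "a", 180), _band("m", "b")) == "no_amp"

    def test_multiple_bands_are_ambiguous(self):
        assert classify_pair(_band("m", "a", 180, 300), _band("m", "b", 150)) == "ambiguous"

    def test_symmetry(self):
        for x, y in [
            (_band("m", "a", 180), _band("m", "b", 150)),
            (_band("m", "a"), _band("m", "b", 150)),
            (_band("m", "a", 100, 200), _band("m", "b", 150)),
        ]:
            assert classify_pair(x, y) == classify_pair(y, x)


def _matrix(cells, species=None, roles=None):
    """cells: dict marker -> dict accession -> sizes tuple (() = no amp)."""
    results = {
        mk: {acc: _band(mk, acc, *sizes) for acc, sizes in row.items()}
        for mk, row in cells.items()
    }
    accs = list(next(iter(cells.values())))
    species = species or {a: a for a in accs}
    roles = roles or {a: "wild" for a in accs}
    return BandMatrix(results, species, roles)


class TestSummarizeMatrix:
    def test_saturated_matrix_is_fully_polymorphic(self):
        cells = {
            f"m{i}": {"CULT": (200,), "W1": (250,), "W2": (300,)}
            for i in range(10)
        }
        m = _matrix(cells, roles={"CULT": "cultivar", "W1": "wild", "W2": "wild"})
        s = summarize_matrix(m, ["CULT"])
        assert s.overall_polymorphic == 10
        assert s.percentage == 100.0
        assert s.polymorphic_counts["W1"]["CULT"] == 10
        assert s.no_amp_counts == {"W1": 0, "W2": 0}

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_per_cell_recount(self, seed):
        rng = np.random.default_rng(seed)
        markers = [f"m{i}" for i in range(30)]
        accs = ["C1", "C2", "W1", "W2", "W3"]
        cells = {}
        for mk in markers:
            row = {}
            for acc in accs:
                r = rng.random()
                if r < 0.1:
                    row[acc] = ()
                elif r < 0.2:
                    row[acc] = (150, 400)
                else:
                    row[acc] = (int(rng.integers(100, 400)),)
            cells[mk] = row
        m = _matrix(cells)
        s = summarize_matrix(m, ["C1", "C2"])
        # independent recount
        for w in ("W1", "W2", "W3"):
            for c in ("C1", "C2"):
                expect = 0
                for mk in markers:
                    a, b = cells[mk][w], cells[mk][c]
                    if len(a) == 1 and len(b) == 1 and abs(a[0] - b[0]) >= 20:
                        expect += 1
                assert s.polymorphic_counts[w][c] == expect
            assert s.no_amp_counts[w] == sum(1 for mk in markers if cells[mk][w] == ())

    def test_totals_invariant_under_permutation(self):
        rng = np.random.default_rng(9)
        markers = [f"m{i}" for i in range(15)]
        cells = {
            mk: {a: (int(rng.integers(100, 400)),) for a in ("C1", "W1", "W2")}
            for mk in markers
        }
        m1 = _matrix(cells)
        shuffled = dict(reversed(list(cells.items())))
        m2 = _matrix(shuffled)
        s1 = summarize_matrix(m1, ["C1"])
        s2 = summarize_matrix(m2, ["C1"])
        assert s1.overall_polymorphic == s2.overall_polymorphic
        assert s1.polymorphic_counts == s2.polymorphic_counts

    def test_unknown_cultivar_rejected(self):
        m = _matrix({"m0": {"A": (100,), "B": (200,)}})
        with pytest.raises(ValueError):
            summarize_matrix(m, ["NOPE"])


class TestSpeciesSpecific:
    SPECIES = {"A1": "spA", "A2": "spA", "B1": "spB", "B2": "spB", "C1": "spC"}

    def test_private_shared_band_is_diagnostic(self):
        m = _matrix({"m0": {"A1": (300,), "A2": (300,), "B1": (250,),
                            "B2": (260,), "C1": (250,)}})
        hits = find_species_specific(m, self.SPECIES)
        assert [(h[0], h[1]) for h in hits] == [("m0", "spA")]

    def test_one_deviating_accession_breaks_diagnosis(self):
        m = _matrix({"m0": {"A1": (300,), "A2": (250,), "B1": (250,),
                            "B2": (260,), "C1": (250,)}})
        assert all(h[1] != "spA" for h in find_species_specific(m, self.SPECIES))

    def test_uniform_no_amp_can_be_diagnostic(self):
        m = _matrix({"m0": {"A1": (), "A2": (), "B1": (250,),
                            "B2": (260,), "C1": (250,)}})
        hits = find_species_specific(m, self.SPECIES)
        assert ("m0", "spA", "no amplification") in hits

    def test_planted_private_alleles_exactly_recovered(self):
        rng = np.random.default_rng(4)
        cells = {}
        diagnostic = {f"d{i}" for i in range(5)}
        for mk in [f"d{i}" for i in range(5)] + [f"n{i}" for i in range(15)]:
            base = int(rng.integers(150, 350))
            if mk in diagnostic:
                row = {a: ((base + 60,) if sp == "spA" else (base,))
                       for a, sp in self.SPECIES.items()}
            else:
                row = {a: (base,) for a in self.SPECIES}
            cells[mk] = row
        hits = find_species_specific(_matrix(cells), self.SPECIES)
        assert {h[0] for h in hits if h[1] == "spA"} == diagnostic
        assert all(h[1] == "spA" for h in hits)

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            find_species_specific(_matrix({"m0": {"A1": (100,)}}), {"A1": "spA"})


class TestGenotyping:
    def test_wild_band_calls_introgression(self):
        gt = call_genotypes(_band("m", "bc", 150), rice_band=180, wild_band=150)
        assert gt.call == "wild"

    def test_both_parental_bands_call_heterozygous(self):
        gt = call_genotypes(_band("m", "f1", 150, 180), rice_band=180, wild_band=150)
        assert gt.call == "heterozygous"

    def test_no_band_fails(self):
        gt = call_genotypes(_band("m", "x"), rice_band=180, wild_band=150)
        assert gt.call == "fail"

    def test_unresolvable_parents_error(self):
        with pytest.raises(ValueError):
            call_genotypes(_band("m", "x", 150), rice_band=160, wild_band=150)


class TestIntervalStats:
    def test_printed_mean_intervals(self):
        lengths = load_rice_chromosome_lengths()
        assert sum(lengths.values()) == 373_245_519
        assert marker_interval_stats(172, lengths)["mean_interval_mb"] == 2.17
        assert marker_interval_stats(259, lengths)["mean_interval_mb"] == 1.44

    def test_single_marker_single_chromosome(self):
        assert marker_interval_stats(1, {"c": 2_000_000})["mean_interval_mb"] == 2.0

    def test_positions_give_max_gap(self):
        stats = marker_interval_stats(
            [("c", 500_000), ("c", 1_500_000)], {"c": 4_000_000}
        )
        assert stats["max_gap_mb"]["c"] == 2.5
        assert stats["marker_count"] == 2

    def test_zero_markers_error(self):
        with pytest.raises(ValueError):
            marker_interval_stats(0, {"c": 1_000})


class TestValidationCountTable:
    def test_packaged_table_reproduces_printed_figures(self):
        table = load_validation_table()
        stats = summarize_counts_table(table, designed_count=182)
        assert stats["max_poly_vs_nipponbare"] == 172
        assert stats["max_poly_vs_ir24"] == 171
        assert stats["CC_min_poly_vs_nipponbare"] == 164
        assert stats["CC_min_poly_vs_ir24"] == 162
        assert stats["BBCC_range"] == (153, 169)
        assert stats["BBCC_pct_range"] == (84.1, 92.9)
        assert stats["overall_polymorphic"] == 172
        assert stats["overall_percentage"] == 94.5
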