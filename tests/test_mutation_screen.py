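"""Lineage-exclusive substitution screen against the conservation panel."""

import numpy as np
import pytest

from foxcomp.mutation_screen import (
    DEFAULT_GROUPS,
    PanelAlignment,
    classify_column,
    screen_gene,
    screen_quartets,
)
from foxcomp.seqcore import GENETIC_CODE, SENSE_CODONS, CodingSequence, translate
from foxcomp.simulate import (
    DEFAULT_TAXA,
    FIGURE_PLANTS,
    PlantSpec,
    generate_ancestral_cds,
    generate_panel,
)

PANEL_ONLY = [t for t in DEFAULT_TAXA if t not in DEFAULT_GROUPS]
GROUPS = {t: DEFAULT_GROUPS.get(t, "panel") for t in DEFAULT_TAXA}


def _column(default, **overrides):
    col = {t: default for t in DEFAULT_TAXA}
    col.update(overrides)
    return col


class TestClassifyColumn:
    def test_wild_specific(self):
        col = _column("W", AF="R", RF="R")
        assert classify_column(col, GROUPS) == ("wild_specific", ("AF", "RF"), "W", "R")

    def test_farmed_species_specific(self):
        col = _column("K", SF="N")
        category, focal, bg, derived = classify_column(col, GROUPS)
        assert (category, focal, bg, derived) == (
            "farmed_species_specific", ("SF",), "K", "N",
        )

    def test_shared_farmed(self):
        col = _column("A", BF="S", SF="S")
        assert classify_column(col, GROUPS) == (
            "shared_farmed", ("BF", "SF"), "A", "S",
        )

    def test_panel_polymorphism_disqualifies(self):
        col = _column("W", AF="R", RF="R", dog="L", cat="V")
        assert classify_column(col, GROUPS) is None

    def test_tolerance_admits_k_panel_mismatches(self):
        col = _column("W", AF="R", RF="R", dog="L")
        assert classify_column(col, GROUPS) is None
        assert classify_column(col, GROUPS, max_panel_mismatches=1) is not None

    def test_focal_residue_in_panel_disqualifies(self):
        col = _column("K", SF="N", horse="N")
        assert classify_column(col, GROUPS) is None

    def test_ambiguous_residue_skipped(self):
        col = _column("K", SF="N", dog="X")
        assert classify_column(col, GROUPS) is None

    def test_invariant_column_none(self):
        assert classify_column(_column("G"), GROUPS) is None


def _panel_from(plants, n_codons=200, seed=31, gene="g"):
    base = CodingSequence(gene, generate_ancestral_cds(n_codons, seed=seed).seq)
    seqs = generate_panel(base, plants)
    return PanelAlignment(gene, {t: c.seq for t, c in seqs.items()}, GROUPS)


class TestScreenGene:
    def test_figure_fixture_recovers_all_three(self, figure_panels):
        by_site = {}
        for gene_id, (plant, panel) in figure_panels.items():
            pa = PanelAlignment(gene_id, {t: c.seq for t, c in panel.items()}, GROUPS)
            sites = screen_gene(pa)
            assert len(sites) == 1
            by_site[sites[0].nt_site] = sites[0]
        assert set(by_site) == {235, 527, 153}
        assert by_site[235].category == "wild_specific"
        assert (by_site[235].background_aa, by_site[235].derived_aa) == ("W", "R")
        assert by_site[527].category == "farmed_species_specific"
        assert (by_site[527].background_aa, by_site[527].derived_aa) == ("L", "Q")
        assert by_site[153].category == "farmed_species_specific"
        assert (by_site[153].background_aa, by_site[153].derived_aa) == ("K", "N")

    def test_identical_rows_empty(self):
        assert screen_gene(_panel_from([])) == []

    def test_random_plants_recovered_exactly(self):
        """Truth-table oracle: every planted site and nothing else."""
        rng = np.random.default_rng(12)
        base = CodingSequence("g", generate_ancestral_cds(300, seed=13).seq)
        base_codons = base.codons()
        focal_choices = [
            frozenset({"SF"}), frozenset({"BF"}),
            frozenset({"AF", "RF"}), frozenset({"BF", "SF"}),
        ]
        plants = []
        used = set()
        while len(plants) < 10:
            ci = int(rng.integers(2, 300))
            if ci in used:
                continue
            bg = base_codons[ci - 1]
            pos = int(rng.integers(0, 3))
            for alt in "ACGT":
                derived = bg[:pos] + alt + bg[pos + 1 :]
                if (
                    derived != bg
                    and derived not in ("TAA", "TAG", "TGA")
                    and GENETIC_CODE[derived] != GENETIC_CODE[bg]
                ):
                    plants.append(
                        PlantSpec("g", ci, focal_choices[len(plants) % 4], bg, derived)
                    )
                    used.add(ci)
                    break
        seqs = generate_panel(base, plants)
        pa = PanelAlignment("g", {t: c.seq for t, c in seqs.items()}, GROUPS)
        found = {(s.codon_index, s.nt_site, tuple(s.focal_taxa)) for s in screen_gene(pa)}
        expected = {
            (p.codon_index, p.nt_site, tuple(sorted(p.focal_taxa))) for p in plants
        }
        assert found == expected

    def test_taxon_order_invariance(self, figure_panels):
        plant, panel = figure_panels["LEMD2"]
        seqs = {t: c.seq for t, c in panel.items()}
        shuffled = dict(reversed(list(seqs.items())))
        a = screen_gene(PanelAlignment("g", seqs, GROUPS))
        b = screen_gene(PanelAlignment("g", shuffled, GROUPS))
        assert [
            (s.codon_index, s.nt_site, s.category, s.focal_taxa) for s in a
        ] == [(s.codon_index, s.nt_site, s.category, s.focal_taxa) for s in b]

    def test_panel_growth_only_removes_sites(self):
        """Dropping one panel taxon can only keep or add sites, never lose one."""
        plants = [PlantSpec("g", 79, frozenset({"AF", "RF"}), "TGG", "AGG")]
        full = _panel_from(plants)
        full_sites = {(s.codon_index, s.category) for s in screen_gene(full)}
        for drop in PANEL_ONLY:
            seqs = {t: s for t, s in full.sequences.items() if t != drop}
            groups = {t: GROUPS[t] for t in seqs}
            reduced = PanelAlignment("g", seqs, groups)
            reduced_sites = {(s.codon_index, s.category) for s in screen_gene(reduced)}
            assert full_sites <= reduced_sites

    def test_flagged_codons_translate_consistently(self, figure_panels):
        for gene_id, (plant, panel) in figure_panels.items():
            pa = PanelAlignment(gene_id, {t: c.seq for t, c in panel.items()}, GROUPS)
            for s in screen_gene(pa):
                assert translate(plant.derived_codon) == s.derived_aa
                assert translate(plant.background_codon) == s.background_aa

    def test_multi_nt_codon_difference_flagged(self):
        base = CodingSequence("g", generate_ancestral_cds(50, seed=40).seq)
        codons = base.codons()
        ci = 10
        bg = codons[ci - 1]
        seqs = {}
        for t in DEFAULT_TAXA:
            cs = list(codons)
            if t == "SF":
                derived = None
                for cand in SENSE_CODONS:
                    n_diff = sum(x != y for x, y in zip(cand, bg))
                    if n_diff == 2 and GENETIC_CODE[cand] != GENETIC_CODE[bg]:
                        derived = cand
                        break
                cs[ci - 1] = derived
            seqs[t] = "".join(cs)
        pa = PanelAlignment("g", seqs, GROUPS)
        sites = screen_gene(pa)
        assert len(sites) == 1 and sites[0].multi_nt
        assert sites[0].nt_site in range(3 * ci - 2, 3 * ci + 1)


class TestScreenQuartets:
    def test_three_plants_in_three_of_many_genes(self, figure_panels):
        panels = {
            g: PanelAlignment(g, {t: c.seq for t, c in p.items()}, GROUPS)
            for g, (_, p) in figure_panels.items()
        }
        clean = _panel_from([], gene="clean")
        panels["clean"] = clean
        sites, warnings = screen_quartets(list(panels), panels)
        assert len(sites) == 3
        assert warnings == 0
        assert {s.gene_id for s in sites} == {"LEMD2", "RRBP1", "IGBP1"}
        # farmed-specific sites sort before wild-specific ones
        assert [s.category for s in sites] == [
            "farmed_species_specific", "farmed_species_specific", "wild_specific",
        ]

    def test_missing_panels_warn_and_skip(self):
        sites, warnings = screen_quartets(["a", "b", "c"], {})
        assert sites == [] and warnings == 3

    def test_duplicate_gene_ids_single_report(self, figure_panels):
        panels = {
            "LEMD2": PanelAlignment(
                "LEMD2",
                {t: c.seq for t, c in figure_panels["LEMD2"][1].items()},
                GROUPS,
            )
        }
        sites, _ = screen_quartets(["LEMD2", "LEMD2"], panels)
        assert len(sites) == 1
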