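"""Screen a 13-taxon conservation panel for residues carried exclusively by
one fox lineage — the three worked substitutions of the study."""

from foxcomp.mutation_screen import DEFAULT_GROUPS, PanelAlignment, screen_gene
from foxcomp.seqcore import CodingSequence
from foxcomp.simulate import DEFAULT_TAXA, FIGURE_PLANTS, generate_ancestral_cds, generate_panel

groups = {t: DEFAULT_GROUPS.get(t, "panel") for t in DEFAULT_TAXA}
for plant in FIGURE_PLANTS:
    base = CodingSequence(
        plant.gene_id,
        generate_ancestral_cds(max(200, plant.codon_index), seed=3).seq,
    )
    panel = generate_panel(base, [plant])
    pa = PanelAlignment(plant.gene_id, {t: c.seq for t, c in panel.items()}, groups)
    (site,) = screen_gene(pa)
    print(
        f"{site.gene_id}: CDS site {site.nt_site} (codon {site.codon_index}) "
        f"{site.background_aa}->{site.derived_aa} exclusive to "
        f"{','.join(site.focal_taxa)} [{site.category}]"
    )
# Sites 235 (W->R, both wild foxes), 527 (L->Q, silver fox) and 153
# (K->N, silver fox) are recovered at otherwise invariant panel columns.
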