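"""Lineage-exclusive amino-acid substitution screen against a conservation panel.

A column qualifies when a predefined taxon group — both farmed foxes, a
single farmed fox, or the wild pair — carries a residue found in no other
taxon while every other taxon is invariant.  The conservation requirement is
strict by default (any panel polymorphism disqualifies the column); a
tolerance ``max_panel_mismatches`` admits up to k deviating non-focal taxa.
Both directions are screened: a residue exclusive to the wild pair is just
as reportable as one exclusive to a farmed fox.

Nucleotide site numbering is relative to the gene's CDS start, 1-based, so
a first-position change in codon 79 reports site 235.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .seqcore import CodingSequence, codon_to_nt_span, translate

__all__ = [
    "PanelAlignment",
    "FlaggedSite",
    "classify_column",
    "screen_gene",
    "screen_quartets",
    "write_screen_tsv",
    "DEFAULT_GROUPS",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("shared_farmed", "farmed_species_specific", "wild_specific")

#: Group assignment for the study taxa; everything else is panel.
DEFAULT_GROUPS = {
    "AF": "wild_fox",
    "RF": "wild_fox",
    "BF": "farmed_fox",
    "SF": "farmed_fox",
}


@dataclass(frozen=True)
class PanelAlignment:
    """A gap-free-by-construction multi-taxon codon alignment for one gene."""

    gene_id: str
    sequences: Mapping[str, str]  # taxon -> aligned CDS (codon data)
    groups: Mapping[str, str]     # taxon -> wild_fox | farmed_fox | panel

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths in panel {self.gene_id!r}")
        length = lengths.pop()
        if length % 3 != 0:
            raise ValueError(f"panel {self.gene_id!r} length {length} not codon-sized")
        missing = set(self.sequences) - set(self.groups)
        if missing:
            raise ValueError(f"taxa without group assignment: {sorted(missing)}")
        n_panel = sum(
            1 for t in self.sequences if self.groups[t] == "panel"
        )
        if n_panel < 2:
            raise ValueError("need at least 2 panel taxa for a conservation check")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codon_column(self, codon_index: int) -> dict[str, str]:
        """1-based codon column as taxon -> codon."""
        a, b = codon_to_nt_span(codon_index)
        return {t: s[a - 1 : b] for t, s in self.sequences.items()}


@dataclass(frozen=True)
class FlaggedSite:
    """One lineage-exclusive substitution."""

    gene_id: str
    codon_index: int
    nt_site: int | None  # 1-based CDS position of the differing nucleotide
    category: str
    focal_taxa: tuple[str, ...]
    background_aa: str
    derived_aa: str
    multi_nt: bool = False  # codon differs at >1 position; nt_site = first

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.derived_aa == self.background_aa:
            raise ValueError("derived residue equals background")


def classify_column(
    column: Mapping[str, str],
    groups: Mapping[str, str],
    max_panel_mismatches: int = 0,
) -> tuple[str, tuple[str, ...], str, str] | None:
    """Classify one residue column; None when no group-exclusive pattern holds.

    Returns (category, focal taxa, background residue, derived residue).
    Candidate focal groups are {BF, SF} shared, each farmed fox alone, and
    the wild pair {AF, RF}.  The focal residue must be shared by the focal
    taxa and absent from all others; non-focal taxa must be invariant, up to
    ``max_panel_mismatches`` deviations from their majority residue (the
    focal residue never counts as an admissible deviation).
    """
    if any(aa == "X" for aa in column.values()):
        logger.debug("column with ambiguous residue skipped")
        return None
    farmed = sorted(t for t, g in groups.items() if g == "farmed_fox" and t in column)
    wild = sorted(t for t, g in groups.items() if g == "wild_fox" and t in column)
    candidates: list[tuple[str, tuple[str, ...]]] = []
    if len(farmed) >= 2:
        candidates.append(("shared_farmed", tuple(farmed)))
    for t in farmed:
        candidates.append(("farmed_species_specific", (t,)))
    if len(wild) >= 2:
        candidates.append(("wild_specific", tuple(wild)))
    for category, focal in candidates:
        focal_res = {column[t] for t in focal}
        if len(focal_res) != 1:
            continue
        derived = focal_res.pop()
        rest = [column[t] for t in column if t not in focal]
        if not rest or derived in rest:
            continue
        counts = Counter(rest)
        background, n_bg = counts.most_common(1)[0]
        if len(rest) - n_bg > max_panel_mismatches:
            continue
        if derived == background:
            continue
        return category, focal, background, derived
    return None


def _codon_diff_site(
    codon_index: int, derived_codon: str, background_codon: str
) -> tuple[int | None, bool]:
    diffs = [i for i in range(3) if derived_codon[i] != background_codon[i]]
    if not diffs:
        return None, False
    start, _ = codon_to_nt_span(codon_index)
    return start + diffs[0], len(diffs) > 1


def screen_gene(
    panel: PanelAlignment, max_panel_mismatches: int = 0
) -> list[FlaggedSite]:
    """All lineage-exclusive substitutions in one gene's panel.

    Columns with gaps or ambiguous codons are skipped.  The nucleotide site
    is the single position at which the focal (derived) codon differs from
    the majority background codon of the non-focal taxa; multi-nucleotide
    codon differences report the first differing position and are flagged.
    """
    flagged: list[FlaggedSite] = []
    for ci in range(1, panel.n_codons + 1):
        codons = panel.codon_column(ci)
        if any("-" in c or "N" in c for c in codons.values()):
            continue
        residues = {t: translate(c) for t, c in codons.items()}
        if any(r == "*" for r in residues.values()):
            continue
        hit = classify_column(residues, panel.groups, max_panel_mismatches)
        if hit is None:
            continue
        category, focal, background_aa, derived_aa = hit
        derived_codon = codons[focal[0]]
        background_codons = Counter(
            codons[t]
            for t in codons
            if t not in focal and residues[t] == background_aa
        )
        background_codon = background_codons.most_common(1)[0][0]
        nt_site, multi = _codon_diff_site(ci, derived_codon, background_codon)
        flagged.append(
            FlaggedSite(
                gene_id=panel.gene_id,
                codon_index=ci,
                nt_site=nt_site,
                category=category,
                focal_taxa=focal,
                background_aa=background_aa,
                derived_aa=derived_aa,
                multi_nt=multi,
            )
        )
    return flagged


def screen_quartets(
    gene_ids: Iterable[str],
    panels: Mapping[str, PanelAlignment],
    max_panel_mismatches: int = 0,
) -> tuple[list[FlaggedSite], int]:
    """Screen every quartet gene with an available panel.

    Returns the aggregated flagged sites — genes with hits first, sorted by
    category then gene id — and the count of genes skipped for lack of a
    panel (each skip logs a warning).
    """
    sites: list[FlaggedSite] = []
    warnings = 0
    for gene in sorted(set(gene_ids)):
        panel = panels.get(gene)
        if panel is None:
            logger.warning("no conservation panel for gene %s; skipped", gene)
            warnings += 1
            continue
        sites.extend(screen_gene(panel, max_panel_mismatches))
    sites.sort(key=lambda s: (s.category, s.gene_id, s.codon_index))
    return sites, warnings


def write_screen_tsv(sites: Iterable[FlaggedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tcodon_index\tnt_site\tcategory\tfocal_taxa\t"
            "background_aa\tderived_aa\tmulti_nt\n"
        )
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.codon_index}\t{s.nt_site or ''}\t{s.category}\t"
                f"{','.join(s.focal_taxa)}\t{s.background_aa}\t{s.derived_aa}\t"
                f"{int(s.multi_nt)}\n"
            )
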