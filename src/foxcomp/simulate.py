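"""Synthetic study inputs: ortholog quartets evolved under controlled omega,
conservation panels with planted group-exclusive substitutions, and unigenes
with planted SSR motifs.

The generator emulates the study design — two wild/farmed pairs (arctic fox
AF / blue fox BF and red fox RF / silver fox SF), a mammalian conservation
panel, and transcriptome-style unigene sets — so every pipeline stage can be
exercised and scored against written truth tables without the original
sequencing data.

Substitutions follow an acceptance-ratio scheme rather than a full codon
rate matrix: each event proposes a uniform single-nucleotide change at a
uniform site, rejects changes creating stops, and accepts synonymous
proposals with probability min(1, 1/omega) and nonsynonymous ones with
min(1, omega).  The realised nonsynonymous:synonymous substitution ratio
therefore scales with omega relative to the neutral site ratio, which is
exactly what a counting estimator measures.  Lineages evolve independently
from the ancestor (star topology), so pairwise divergence is the sum of two
lineages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqcore import (
    BASES,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodingSequence,
    NucSequence,
    codon_to_nt_span,
    write_fasta,
)

__all__ = [
    "SimConfig",
    "PlantSpec",
    "generate_ancestral_cds",
    "evolve_pair",
    "evolve_lineage",
    "generate_panel",
    "plant_ssr",
    "generate_study",
    "DEFAULT_TAXA",
    "PANEL_TAXA",
    "FIGURE_PLANTS",
]

FOX_TAXA = ("AF", "BF", "RF", "SF")
#: Nine panel mammals spanning Carnivora, Artiodactyla, Perissodactyla and
#: Cetacea, standing in for the study's download of major mammalian lineages.
PANEL_TAXA = (
    "dog", "cat", "giant_panda", "ferret", "tiger",
    "cattle", "sheep", "horse", "dolphin",
)
DEFAULT_TAXA = FOX_TAXA + PANEL_TAXA  # 13 taxa


@dataclass(frozen=True)
class PlantSpec:
    """One planted group-exclusive substitution in a conservation panel."""

    gene_id: str
    codon_index: int  # 1-based
    focal_taxa: frozenset[str]
    background_codon: str
    derived_codon: str

    def __post_init__(self) -> None:
        if self.background_codon in STOP_CODONS or self.derived_codon in STOP_CODONS:
            raise ValueError("planted codons must be non-stop")
        diff = [
            i for i in range(3) if self.background_codon[i] != self.derived_codon[i]
        ]
        if len(diff) != 1:
            raise ValueError(
                "background and derived codons must differ at exactly one position"
            )

    @property
    def nt_site(self) -> int:
        """1-based CDS position of the single differing nucleotide."""
        start, _ = codon_to_nt_span(self.codon_index)
        diff = next(
            i for i in range(3) if self.background_codon[i] != self.derived_codon[i]
        )
        return start + diff


#: The three worked substitutions the screen must recover: a wild-fox-shared
#: W->R at CDS site 235, a silver-fox L->Q at 527, a silver-fox K->N at 153.
FIGURE_PLANTS = (
    PlantSpec("LEMD2", 79, frozenset({"AF", "RF"}), "TGG", "AGG"),    # site 235 W->R
    PlantSpec("RRBP1", 176, frozenset({"SF"}), "CTA", "CAA"),         # site 527 L->Q
    PlantSpec("IGBP1", 51, frozenset({"SF"}), "AAG", "AAC"),          # site 153 K->N
)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale knobs for :func:`generate_study`.

    Defaults give a desk-scale study: 20 ortholog quartets of 200 codons,
    most evolving under purifying selection (omega 0.2) with a few under
    positive selection (omega 3), 60 substitution events per lineage, the
    three worked panel plants, and SSR-bearing unigenes.
    """

    n_genes: int = 20
    n_codons: int = 200
    omega_target: float = 0.2
    omega_positive: float = 3.0
    n_positive: int = 3
    n_substitution_events: int = 60
    seed: int = 0
    taxa: tuple[str, ...] = DEFAULT_TAXA
    n_ssr_seqs: int = 20
    utr_len: int = 45

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.omega_target <= 0 or self.omega_positive <= 0:
            raise ValueError("omega must be > 0")
        if not 0 <= self.n_positive <= self.n_genes:
            raise ValueError("n_positive must be within [0, n_genes]")


def _rng(seed: int, *context: object) -> np.random.Generator:
    """Independent, reproducible stream per (seed, context) pair."""
    digest = hashlib.sha256(("|".join(map(str, context))).encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng((seed, sub))


def generate_ancestral_cds(n_codons: int, seed: int) -> CodingSequence:
    """A random frame-valid CDS: ATG followed by uniform non-stop codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _rng(seed, "ancestor", n_codons)
    body = [c for c in SENSE_CODONS if c != "ATG"]
    codons = ["ATG"] + [body[i] for i in rng.integers(0, len(body), n_codons - 1)]
    return CodingSequence(f"anc_{seed}", "".join(codons))


def evolve_lineage(
    ancestor: CodingSequence, omega: float, n_events: int, rng: np.random.Generator
) -> str:
    """Apply the acceptance-ratio substitution process along one lineage."""
    seq = list(ancestor.seq)
    if len(seq) <= 3:  # nothing but the (fixed) start codon
        return "".join(seq)
    p_syn = min(1.0, 1.0 / omega)
    p_non = min(1.0, omega)
    for _ in range(n_events):
        # the start codon is held fixed (ORF recovery depends on it)
        site = int(rng.integers(3, len(seq)))
        base = BASES[int(rng.integers(0, 4))]
        if base == seq[site]:
            continue
        codon_start = (site // 3) * 3
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = (
            old_codon[: site - codon_start] + base + old_codon[site - codon_start + 1 :]
        )
        if new_codon in STOP_CODONS:
            continue  # reject stop-creating proposals
        synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
        accept = p_syn if synonymous else p_non
        if rng.random() < accept:
            seq[site] = base
    return "".join(seq)


def evolve_pair(
    ancestor: CodingSequence, omega: float, n_events: int, seed: int
) -> tuple[CodingSequence, CodingSequence]:
    """Evolve two independent descendants of ``ancestor`` (star topology).

    Each lineage receives ``n_events`` proposal events, so the expected
    pairwise divergence is twice the per-lineage one.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng_a = _rng(seed, "lineageA", ancestor.id)
    rng_b = _rng(seed, "lineageB", ancestor.id)
    seq_a = evolve_lineage(ancestor, omega, n_events, rng_a)
    seq_b = evolve_lineage(ancestor, omega, n_events, rng_b)
    return (
        CodingSequence(f"{ancestor.id}_d1", seq_a),
        CodingSequence(f"{ancestor.id}_d2", seq_b),
    )


def generate_panel(
    base: CodingSequence,
    plants: list[PlantSpec] | tuple[PlantSpec, ...],
    taxa: tuple[str, ...] = DEFAULT_TAXA,
) -> dict[str, CodingSequence]:
    """Build a gap-free codon panel: all taxa identical to ``base`` except at
    planted codons, where exactly the focal taxa carry the derived codon and
    every other taxon the background codon."""
    seen: set[int] = set()
    for p in plants:
        if p.codon_index in seen:
            raise ValueError(f"overlapping plants at codon {p.codon_index}")
        seen.add(p.codon_index)
        if p.codon_index > base.n_codons:
            raise ValueError(
                f"plant codon {p.codon_index} beyond base length {base.n_codons}"
            )
        missing = p.focal_taxa - set(taxa)
        if missing:
            raise ValueError(f"focal taxa {sorted(missing)} not in panel taxa")
    panel: dict[str, CodingSequence] = {}
    for taxon in taxa:
        codons = base.codons()
        for p in plants:
            codons[p.codon_index - 1] = (
                p.derived_codon if taxon in p.focal_taxa else p.background_codon
            )
        panel[taxon] = CodingSequence(f"{base.id}_{taxon}", "".join(codons))
    return panel


def plant_ssr(seq: NucSequence, motif: str, repeats: int, position: int) -> NucSequence:
    """Overwrite ``seq`` with ``motif * repeats`` starting at 1-based ``position``."""
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1-6")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    tract = motif * repeats
    if position < 1 or position + len(tract) - 1 > len(seq):
        raise ValueError(
            f"SSR of length {len(tract)} at position {position} "
            f"does not fit in sequence of length {len(seq)}"
        )
    i = position - 1
    return NucSequence(seq.id, seq.seq[:i] + tract + seq.seq[i + len(tract) :])


def _random_background(length: int, rng: np.random.Generator) -> str:
    """Repeat-free-ish random nucleotides: rejects any >=2-unit tandem of
    units 1-6 long enough to reach detection thresholds by breaking it."""
    from .ssr import SSRThresholds, detect_ssrs  # local import, no cycle at load

    while True:
        s = "".join(BASES[i] for i in rng.integers(0, 4, length))
        if not detect_ssrs(NucSequence("bg", s), SSRThresholds()):
            return s


def _utr(length: int, rng: np.random.Generator) -> str:
    """UTR filler free of ATG (keeps planted ORFs unambiguous) on both strands."""
    while True:
        s = "".join(BASES[i] for i in rng.integers(0, 4, length))
        if "ATG" not in s and "CAT" not in s:
            return s


def generate_study(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic study to ``out_dir`` and return the file map.

    Emits per-taxon CDS and unigene FASTAs for the AF/BF and RF/SF quartets
    with a per-gene true-omega table, panel FASTAs with plant truth, an
    SSR-bearing unigene FASTA with locus truth, and the config (seed
    included) as YAML.  Byte-identical output under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    seed = config.seed

    # --- ortholog quartets under controlled omega -------------------------
    omegas = [
        config.omega_positive if g < config.n_positive else config.omega_target
        for g in range(config.n_genes)
    ]
    per_taxon: dict[str, list[CodingSequence]] = {t: [] for t in FOX_TAXA}
    unigenes: dict[str, list[NucSequence]] = {t: [] for t in FOX_TAXA}
    outgroup_cds: list[CodingSequence] = []
    truth_rows = []
    for g in range(config.n_genes):
        gene = f"gene{g + 1:04d}"
        anc = CodingSequence(gene, generate_ancestral_cds(config.n_codons, seed + g).seq)
        omega = omegas[g]
        # a deeply diverged outgroup lineage (giant panda in the study's tree)
        rng_og = _rng(seed, "lineage", gene, "outgroup")
        og_seq = evolve_lineage(anc, 0.2, 4 * config.n_substitution_events, rng_og)
        outgroup_cds.append(CodingSequence(f"{gene}_giant_panda", og_seq))
        # shared group branches plant the ((AF,BF),(RF,SF)) topology; within a
        # pair, divergence is still the sum of two independent tip lineages
        group_anc = {}
        for group, members in (("wild_pair", ("AF", "BF")), ("red_pair", ("RF", "SF"))):
            rng_g = _rng(seed, "lineage", gene, group)
            ga = evolve_lineage(anc, omega, config.n_substitution_events, rng_g)
            for m in members:
                group_anc[m] = ga
        for taxon in FOX_TAXA:
            rng = _rng(seed, "lineage", gene, taxon)
            seq = evolve_lineage(
                CodingSequence(gene, group_anc[taxon]),
                omega,
                config.n_substitution_events,
                rng,
            )
            cds = CodingSequence(f"{gene}_{taxon}", seq)
            per_taxon[taxon].append(cds)
            rng_u = _rng(seed, "utr", gene, taxon)
            stop = "TAA"
            uni = NucSequence(
                f"{gene}_{taxon}",
                _utr(config.utr_len, rng_u) + seq + stop + _utr(config.utr_len, rng_u),
            )
            unigenes[taxon].append(uni)
        truth_rows.append((gene, f"{omega:g}"))
    for taxon in FOX_TAXA:
        p = out / f"cds_{taxon}.fasta"
        write_fasta(per_taxon[taxon], p)
        files[f"cds_{taxon}"] = p
        p = out / f"unigenes_{taxon}.fasta"
        write_fasta(unigenes[taxon], p)
        files[f"unigenes_{taxon}"] = p
    p = out / "cds_outgroup.fasta"
    write_fasta(outgroup_cds, p)
    files["cds_outgroup"] = p
    p = out / "truth_omega.tsv"
    with open(p, "w") as fh:
        fh.write("gene\ttrue_omega\n")
        for gene, om in truth_rows:
            fh.write(f"{gene}\t{om}\n")
    files["truth_omega"] = p

    # --- conservation panels with the three worked plants -----------------
    panel_dir = out / "panels"
    panel_dir.mkdir(exist_ok=True)
    plant_rows = []
    for plant in FIGURE_PLANTS:
        n_codons = max(config.n_codons, plant.codon_index)
        base = CodingSequence(
            plant.gene_id, generate_ancestral_cds(n_codons, seed + hash_stable(plant.gene_id)).seq
        )
        panel = generate_panel(base, [plant], config.taxa)
        p = panel_dir / f"{plant.gene_id}.fasta"
        write_fasta(
            [CodingSequence(t, panel[t].seq) for t in config.taxa], p
        )
        files[f"panel_{plant.gene_id}"] = p
        plant_rows.append(
            (
                plant.gene_id,
                plant.codon_index,
                plant.nt_site,
                ",".join(sorted(plant.focal_taxa)),
                GENETIC_CODE[plant.background_codon],
                GENETIC_CODE[plant.derived_codon],
            )
        )
    p = out / "truth_plants.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tcodon_index\tnt_site\tfocal_taxa\tbackground_aa\tderived_aa\n")
        for row in plant_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    files["truth_plants"] = p

    # --- SSR-bearing unigenes ---------------------------------------------
    from .ssr import SSRThresholds, detect_ssrs  # deferred import, no load cycle

    thresholds = SSRThresholds()
    motifs = ["A", "AC", "AAG", "ATCG", "AATCG", "AATCGG"]
    ssr_rows = []
    ssr_seqs = []
    rng = _rng(seed, "ssr")
    for i in range(config.n_ssr_seqs):
        sid = f"ssr_seq{i + 1:03d}"
        if i % 4 == 3:  # every fourth sequence stays repeat-free
            seq = NucSequence(sid, _random_background(400, _rng(seed, "ssr_bg", i)))
        else:
            motif = motifs[i % len(motifs)]
            reps = thresholds.min_repeats[len(motif)] + int(rng.integers(0, 4))
            pos = int(rng.integers(50, 400 - len(motif) * reps - 50))
            # flank adjacency can extend a planted tract and shift the truth
            # coordinates; regenerate the background until detection returns
            # exactly the planted locus
            for attempt in range(50):
                bg = _random_background(400, _rng(seed, "ssr_bg", i, attempt))
                seq = plant_ssr(NucSequence(sid, bg), motif, reps, pos)
                found = detect_ssrs(seq, thresholds)
                if len(found) == 1 and (
                    found[0].motif,
                    found[0].repeats,
                    found[0].start,
                ) == (motif, reps, pos):
                    break
            else:  # pragma: no cover - 50 failures is astronomically unlikely
                raise RuntimeError(f"could not place SSR fixture for {sid}")
            ssr_rows.append((sid, motif, reps, pos, pos + len(motif) * reps - 1))
        ssr_seqs.append(seq)
    p = out / "ssr_unigenes.fasta"
    write_fasta(ssr_seqs, p)
    files["ssr_unigenes"] = p
    p = out / "truth_ssr.tsv"
    with open(p, "w") as fh:
        fh.write("seq_id\tmotif\trepeats\tstart\tend\n")
        for row in ssr_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    files["truth_ssr"] = p

    # --- config + seed record ---------------------------------------------
    p = out / "config.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(
            {
                "n_genes": config.n_genes,
                "n_codons": config.n_codons,
                "omega_target": config.omega_target,
                "omega_positive": config.omega_positive,
                "n_positive": config.n_positive,
                "n_substitution_events": config.n_substitution_events,
                "seed": config.seed,
                "taxa": list(config.taxa),
                "n_ssr_seqs": config.n_ssr_seqs,
                "utr_len": config.utr_len,
            },
            fh,
            sort_keys=True,
        )
    files["config"] = p
    return files


def hash_stable(text: str) -> int:
    """Deterministic small non-negative int from a string (process-stable)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:3], "big")
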