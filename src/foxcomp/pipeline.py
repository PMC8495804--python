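"""End-to-end orchestration: synthetic study (or user FASTAs) -> CDS
extraction -> ortholog pairing -> codon-aware Ka/Ks -> positive-selection
table -> lineage-exclusive screen -> SSRs -> enrichment -> tree.

All intermediates are headered TSVs; the bundle is deterministic under a
fixed seed and config (no wall-clock, no filesystem-order dependence), so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import hypergeom_enrich, read_term_map, write_enrichment_tsv
from .kaks import codon_aware_align, kaks
from .mutation_screen import (
    DEFAULT_GROUPS,
    PanelAlignment,
    screen_quartets,
    write_screen_tsv,
)
from .ortholog import join_quartets, reciprocal_best_hits, write_pairs_tsv
from .phylo import bootstrap_support, concat_alignment
from .seqcore import CodingSequence, find_longest_orf, read_fasta, translate
from .simulate import DEFAULT_TAXA, SimConfig, generate_study
from .ssr import SSRThresholds, detect_ssrs, merge_compound, write_misa_table

logger = logging.getLogger(__name__)

FOX_TAXA = ("AF", "BF", "RF", "SF")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and thresholds for a full run.

    When ``simulate`` is true the inputs are generated into
    ``out_dir/fixture`` first; otherwise ``unigene_fastas`` must map each
    of AF, BF, RF, SF to a FASTA path.
    """

    out_dir: Path
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    unigene_fastas: dict[str, Path] = field(default_factory=dict)
    panel_dir: Path | None = None
    term_map_tsv: Path | None = None
    min_cds_len: int = 300
    min_coverage: float = 0.5
    screen_tolerance: int = 0
    bootstrap_reps: int = 100
    ssr_thresholds: SSRThresholds = field(default_factory=SSRThresholds)
    outgroup: str = "giant_panda"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "out_dir", "seed", "simulate", "min_cds_len", "min_coverage",
            "screen_tolerance", "bootstrap_reps", "outgroup",
        }
        unknown = set(raw) - known - {"unigene_fastas", "panel_dir", "term_map_tsv", "sim"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: raw[k] for k in known & set(raw)}
        kwargs["out_dir"] = Path(raw["out_dir"])
        if "unigene_fastas" in raw:
            kwargs["unigene_fastas"] = {
                t: Path(p) for t, p in raw["unigene_fastas"].items()
            }
        if "panel_dir" in raw:
            kwargs["panel_dir"] = Path(raw["panel_dir"])
        if "term_map_tsv" in raw:
            kwargs["term_map_tsv"] = Path(raw["term_map_tsv"])
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        return cls(**kwargs)


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration; output location excluded so the
    same analysis written elsewhere yields the same bundle bytes."""
    fields = {
        k: v for k, v in vars(config).items()
        if k not in {"out_dir", "unigene_fastas", "panel_dir", "term_map_tsv"}
    }
    return hashlib.sha256(repr(sorted(fields.items(), key=lambda kv: kv[0])).encode()).hexdigest()[:12]


def extract_cds(
    unigenes: dict[str, Path], min_len: int, out_dir: Path
) -> dict[str, dict[str, CodingSequence]]:
    """Longest-ORF extraction with the transcriptome length filter, per taxon."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cds: dict[str, dict[str, CodingSequence]] = {}
    stats_rows = []
    for taxon in sorted(unigenes):
        records = read_fasta(unigenes[taxon])
        kept: dict[str, CodingSequence] = {}
        for sid in sorted(records):
            orf = find_longest_orf(records[sid], min_len)
            if orf is not None:
                kept[sid] = orf
        cds[taxon] = kept
        stats_rows.append((taxon, len(records), len(kept)))
    with open(out_dir / "cds_stats.tsv", "w") as fh:
        fh.write("taxon\tn_unigenes\tn_cds_kept\n")
        for row in stats_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    return cds


def kaks_table(
    pairs, cds_a: dict[str, CodingSequence], cds_b: dict[str, CodingSequence],
    group: str, out_path: Path,
) -> list[dict]:
    rows = []
    for p in pairs:
        aln = codon_aware_align(cds_a[p.gene_id_a], cds_b[p.gene_id_b])
        res = kaks(aln)
        rows.append(
            {
                "gene": p.gene_id_a,
                "Ka": res.Ka,
                "Ks": res.Ks,
                "omega": res.omega,
                "flag": res.selection_flag,
                "note": res.note,
                "group": group,
            }
        )
    with open(out_path, "a") as fh:
        if out_path.stat().st_size == 0:
            fh.write("gene\tKa\tKs\tKa/Ks\tflag\tnote\tgroup\n")
        for r in rows:
            om = "NA" if math.isnan(r["omega"]) else f"{r['omega']:.5f}"
            ka = "NA" if math.isnan(r["Ka"]) else f"{r['Ka']:.5f}"
            ks = "NA" if math.isnan(r["Ks"]) else f"{r['Ks']:.5f}"
            fh.write(
                f"{r['gene']}\t{ka}\t{ks}\t{om}\t{r['flag']}\t{r['note']}\t{r['group']}\n"
            )
    return rows


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns the report-bundle file map.

    Stage failures raise :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = config.sim or SimConfig(seed=config.seed)
        fixture = generate_study(sim, out / "fixture")
        unigene_fastas = {t: fixture[f"unigenes_{t}"] for t in FOX_TAXA}
        panel_dir = (out / "fixture" / "panels") if config.panel_dir is None else config.panel_dir
    else:
        unigene_fastas = config.unigene_fastas
        panel_dir = config.panel_dir
        missing = set(FOX_TAXA) - set(unigene_fastas)
        if missing:
            raise StageError(f"stage inputs: missing unigene FASTA for {sorted(missing)}")

    # --- CDS extraction ---------------------------------------------------
    try:
        cds = extract_cds(unigene_fastas, config.min_cds_len, out)
        files["cds_stats"] = out / "cds_stats.tsv"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage cds: {exc}") from exc

    # --- orthologs --------------------------------------------------------
    try:
        proteins = {
            t: {g: translate(c) for g, c in cds[t].items()} for t in FOX_TAXA
        }
        pairs_wild = reciprocal_best_hits(
            proteins["AF"], proteins["BF"], config.min_coverage
        )
        pairs_red = reciprocal_best_hits(
            proteins["RF"], proteins["SF"], config.min_coverage
        )
        path = out / "orthologs.tsv"
        with open(path, "w") as fh:
            fh.write("group\tgene_A\tgene_B\tscore\tcov_A\tcov_B\n")
            for group, pairs in (("AF versus BF", pairs_wild), ("RF versus SF", pairs_red)):
                for p in pairs:
                    fh.write(
                        f"{group}\t{p.gene_id_a}\t{p.gene_id_b}\t{p.score:g}\t"
                        f"{p.coverage_a:.4f}\t{p.coverage_b:.4f}\n"
                    )
        files["orthologs"] = path
        quartets = join_quartets(
            pairs_wild, pairs_red, proteins["AF"], proteins["RF"], config.min_coverage
        )
    except Exception as exc:
        raise StageError(f"stage orthologs: {exc}") from exc

    # --- Ka/Ks ------------------------------------------------------------
    try:
        path = out / "kaks.tsv"
        path.write_text("")
        rows = kaks_table(pairs_wild, cds["AF"], cds["BF"], "AF versus BF", path)
        rows += kaks_table(pairs_red, cds["RF"], cds["SF"], "RF versus SF", path)
        files["kaks"] = path
        pos_path = out / "positive_selection.tsv"
        with open(pos_path, "w") as fh:
            fh.write("gene\tKa/Ks\tgroup\n")
            for r in sorted(
                (r for r in rows if r["flag"] == "positive"),
                key=lambda r: (r["group"], -r["omega"]),
            ):
                fh.write(f"{r['gene']}\t{r['omega']:.5f}\t{r['group']}\n")
        files["positive_selection"] = pos_path
    except Exception as exc:
        raise StageError(f"stage kaks: {exc}") from exc

    # --- mutation screen --------------------------------------------------
    try:
        panels: dict[str, PanelAlignment] = {}
        if panel_dir is not None and Path(panel_dir).is_dir():
            for fasta in sorted(Path(panel_dir).glob("*.fasta")):
                gene = fasta.stem
                seqs = {sid: rec.seq for sid, rec in read_fasta(fasta).items()}
                groups = {t: DEFAULT_GROUPS.get(t, "panel") for t in seqs}
                panels[gene] = PanelAlignment(gene, seqs, groups)
        screen_genes = sorted(panels) if config.simulate else [q.gene_label for q in quartets]
        sites, n_warn = screen_quartets(screen_genes, panels, config.screen_tolerance)
        write_screen_tsv(sites, out / "screen.tsv")
        files["screen"] = out / "screen.tsv"
        if n_warn:
            logger.warning("%d genes lacked conservation panels", n_warn)
    except Exception as exc:
        raise StageError(f"stage screen: {exc}") from exc

    # --- SSRs -------------------------------------------------------------
    try:
        loci = []
        for taxon in sorted(unigene_fastas):
            records = read_fasta(unigene_fastas[taxon])
            for sid in sorted(records):
                loci.extend(detect_ssrs(records[sid], config.ssr_thresholds))
        if config.simulate:
            ssr_fasta = out / "fixture" / "ssr_unigenes.fasta"
            records = read_fasta(ssr_fasta)
            for sid in sorted(records):
                loci.extend(detect_ssrs(records[sid], config.ssr_thresholds))
        loci.sort(key=lambda l: (l.seq_id, l.start))
        loci = merge_compound(loci, config.ssr_thresholds.max_interruption)
        write_misa_table(loci, out / "ssr.misa.tsv")
        files["ssr"] = out / "ssr.misa.tsv"
    except Exception as exc:
        raise StageError(f"stage ssr: {exc}") from exc

    # --- enrichment -------------------------------------------------------
    try:
        if config.term_map_tsv is not None:
            term_map = read_term_map(config.term_map_tsv)
            study = [
                r.strip().split("\t")[0]
                for r in (out / "positive_selection.tsv").read_text().splitlines()[1:]
            ]
            study = [g for g in study if g in term_map.population]
            records = hypergeom_enrich(study, term_map) if study else []
            write_enrichment_tsv(records, out / "enrichment.tsv")
            files["enrichment"] = out / "enrichment.tsv"
    except Exception as exc:
        raise StageError(f"stage enrichment: {exc}") from exc

    # --- tree -------------------------------------------------------------
    try:
        outgroup_cds: dict[str, CodingSequence] = {}
        if config.simulate:
            og_path = out / "fixture" / "cds_outgroup.fasta"
            if og_path.exists():
                outgroup_cds = {
                    sid: CodingSequence(sid, rec.seq)
                    for sid, rec in read_fasta(og_path).items()
                }
        gene_alns: dict[str, dict[str, str]] = {}
        for q in quartets:
            seqs = {
                "AF": translate(cds["AF"][q.af]),
                "BF": translate(cds["BF"][q.bf]),
                "RF": translate(cds["RF"][q.rf]),
                "SF": translate(cds["SF"][q.sf]),
            }
            gene = q.gene_label.rsplit("_", 1)[0]
            og_id = f"{gene}_{config.outgroup}"
            if og_id in outgroup_cds:
                seqs[config.outgroup] = translate(outgroup_cds[og_id])
            if len({len(s) for s in seqs.values()}) == 1:
                gene_alns[q.gene_label] = seqs
        # drop genes whose taxon sets disagree (outgroup missing for some)
        taxon_sets = {tuple(sorted(a)) for a in gene_alns.values()}
        if len(taxon_sets) > 1:
            widest = max(taxon_sets, key=len)
            gene_alns = {
                g: a for g, a in gene_alns.items() if tuple(sorted(a)) == widest
            }
        if gene_alns:
            matrix = concat_alignment(gene_alns)
            tree = bootstrap_support(
                matrix,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
                outgroup=config.outgroup if config.outgroup in matrix.taxa else None,
            )
            path = out / "tree.nwk"
            path.write_text(str(tree).strip() + "\n")
            files["tree"] = path
    except Exception as exc:
        raise StageError(f"stage tree: {exc}") from exc

    # --- run log ----------------------------------------------------------
    log_path = out / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"foxcomp {__version__}\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"config_hash\t{_config_hash(config)}\n")
        for name in sorted(files):
            fh.write(f"output\t{name}\t{files[name].name}\n")
    files["run_log"] = log_path
    return files
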