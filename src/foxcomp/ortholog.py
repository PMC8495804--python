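"""Single-copy ortholog pairing by reciprocal best hit (RBH).

Proteins are scored by global alignment (BLOSUM62, affine gaps).  A pair is
kept only when each member is the unique top hit of the other and both
coverages clear the threshold; equal-top-score ties exclude the gene — the
conservative single-copy rule.  Quartets join an AF–BF pair with an RF–SF
pair through a cross-group RBH between the wild members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "OrthologPair",
    "OrthologQuartet",
    "score_protein_pair",
    "reciprocal_best_hits",
    "join_quartets",
    "write_pairs_tsv",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    gene_id_b: str
    score: float
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        for cov in (self.coverage_a, self.coverage_b):
            if not 0.0 <= cov <= 1.0:
                raise ValueError(f"coverage {cov} outside [0, 1]")


@dataclass(frozen=True)
class OrthologQuartet:
    """Mutually consistent AF/BF and RF/SF orthologs of one gene."""

    gene_label: str
    af: str
    bf: str
    rf: str
    sf: str
    pair_wild: OrthologPair   # AF-BF
    pair_red: OrthologPair    # RF-SF
    cross: OrthologPair       # AF-RF, the joining evidence


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_aligner = _make_aligner()


def _validate(protein: str, label: str) -> str:
    p = protein.rstrip("*")
    if not p:
        raise ValueError(f"empty protein {label!r}")
    bad = set(p) - AA_ALPHABET
    if bad:
        raise ValueError(f"protein {label!r} has invalid letters {sorted(bad)}")
    return p


def score_protein_pair(a: str, b: str) -> tuple[float, float, float]:
    """Global-alignment score plus per-sequence aligned-fraction coverages.

    Coverage of a member is the fraction of its residues placed opposite a
    residue (not a gap) in the optimal alignment.  Symmetric in its inputs.
    """
    pa, pb = _validate(a, "a"), _validate(b, "b")
    aln = _aligner.align(pa, pb)[0]
    aligned_cols = sum(
        int(ia >= 0 and ib >= 0) for ia, ib in zip(*aln.indices)
    )
    return float(aln.score), aligned_cols / len(pa), aligned_cols / len(pb)


def _best_hits(
    queries: dict[str, str], targets: dict[str, str]
) -> dict[str, tuple[str, float, float, float] | None]:
    """Unique top hit per query, or None on an equal-top-score tie."""
    out: dict[str, tuple[str, float, float, float] | None] = {}
    for qid in sorted(queries):
        best: tuple[str, float, float, float] | None = None
        tied = False
        for tid in sorted(targets):
            score, cov_q, cov_t = score_protein_pair(queries[qid], targets[tid])
            if best is None or score > best[1]:
                best, tied = (tid, score, cov_q, cov_t), False
            elif score == best[1] and tid != best[0]:
                tied = True
        out[qid] = None if tied else best
    return out


def reciprocal_best_hits(
    set_a: dict[str, str], set_b: dict[str, str], min_coverage: float = 0.5
) -> list[OrthologPair]:
    """All reciprocal-best pairs between two protein sets.

    Ties for the top score drop the gene (no arbitrary breaking); both
    coverages must reach ``min_coverage``.  Output is sorted by gene id and
    invariant to input ordering.
    """
    if not set_a or not set_b:
        raise ValueError("both protein sets must be non-empty")
    fwd = _best_hits(set_a, set_b)
    rev = _best_hits(set_b, set_a)
    pairs: list[OrthologPair] = []
    for aid in sorted(set_a):
        hit = fwd[aid]
        if hit is None:
            continue
        bid, score, cov_a, cov_b = hit
        back = rev.get(bid)
        if back is None or back[0] != aid:
            continue
        if cov_a < min_coverage or cov_b < min_coverage:
            continue
        pairs.append(OrthologPair(aid, bid, score, cov_a, cov_b))
    return pairs


def join_quartets(
    pairs_af_bf: list[OrthologPair],
    pairs_rf_sf: list[OrthologPair],
    proteins_af: dict[str, str],
    proteins_rf: dict[str, str],
    min_coverage: float = 0.5,
) -> list[OrthologQuartet]:
    """Join the two groups' pairs through an AF–RF cross-group RBH.

    A quartet exists only where the AF member of an AF–BF pair and the RF
    member of an RF–SF pair are reciprocal best hits of each other.
    """
    af_paired = {p.gene_id_a: p for p in pairs_af_bf}
    rf_paired = {p.gene_id_a: p for p in pairs_rf_sf}
    sub_af = {g: proteins_af[g] for g in af_paired if g in proteins_af}
    sub_rf = {g: proteins_rf[g] for g in rf_paired if g in proteins_rf}
    if not sub_af or not sub_rf:
        return []
    cross = reciprocal_best_hits(sub_af, sub_rf, min_coverage)
    quartets = []
    for cp in cross:
        pw, pr = af_paired[cp.gene_id_a], rf_paired[cp.gene_id_b]
        quartets.append(
            OrthologQuartet(
                gene_label=cp.gene_id_a,
                af=pw.gene_id_a,
                bf=pw.gene_id_b,
                rf=pr.gene_id_a,
                sf=pr.gene_id_b,
                pair_wild=pw,
                pair_red=pr,
                cross=cp,
            )
        )
    quartets.sort(key=lambda q: q.gene_label)
    return quartets


def write_pairs_tsv(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_A\tgene_B\tscore\tcov_A\tcov_B\n")
        for p in pairs:
            fh.write(
                f"{p.gene_id_a}\t{p.gene_id_b}\t{p.score:g}\t"
                f"{p.coverage_a:.4f}\t{p.coverage_b:.4f}\n"
            )
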