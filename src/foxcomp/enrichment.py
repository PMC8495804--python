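"""Term over-representation testing (hypergeometric upper tail) with optional
Benjamini–Hochberg adjustment.

One shared statistic stands behind GO and KEGG style analyses: the
probability of drawing at least ``k`` annotated genes when ``n`` study genes
are sampled without replacement from a population of ``N`` containing ``K``
term members.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["TermMap", "EnrichmentRecord", "hypergeom_enrich", "bh_adjust", "read_term_map"]


@dataclass(frozen=True)
class TermMap:
    """term id -> gene set, with descriptions and the background population."""

    terms: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str]
    population: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            extra = genes - self.population
            if extra:
                raise ValueError(
                    f"term {term!r} has genes outside the population: {sorted(extra)[:5]}"
                )


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    description: str
    k: int  # study genes in the term
    K: int  # population genes in the term
    n: int  # study size
    N: int  # population size
    p_value: float
    genes: tuple[str, ...]


def read_term_map(
    gene_term_tsv: str | Path, descriptions_tsv: str | Path | None = None
) -> TermMap:
    """Build a TermMap from a two-column (gene, term) TSV.

    The default background population is every gene appearing in the
    annotation.  An optional two-column (term, description) TSV supplies
    display names.
    """
    df = pd.read_csv(gene_term_tsv, sep="\t", header=None, names=["gene", "term"])
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        terms.setdefault(str(term), set()).add(str(gene))
    descriptions: dict[str, str] = {}
    if descriptions_tsv is not None:
        dd = pd.read_csv(descriptions_tsv, sep="\t", header=None, names=["term", "desc"])
        descriptions = dict(zip(dd["term"].astype(str), dd["desc"].astype(str)))
    population = frozenset(df["gene"].astype(str))
    return TermMap(
        terms={t: frozenset(g) for t, g in terms.items()},
        descriptions=descriptions,
        population=population,
    )


def hypergeom_enrich(
    study: Iterable[str], term_map: TermMap
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric p per term, sorted by p then term id."""
    study_set = frozenset(study)
    offenders = study_set - term_map.population
    if offenders:
        raise ValueError(
            f"study genes absent from population: {sorted(offenders)}"
        )
    n, N = len(study_set), len(term_map.population)
    records = []
    for term_id in sorted(term_map.terms):
        members = term_map.terms[term_id]
        hits = study_set & members
        k, K = len(hits), len(members)
        # P(X >= k) for X ~ Hypergeom(N, K, n); k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                description=term_map.descriptions.get(term_id, ""),
                k=k, K=K, n=n, N=N,
                p_value=min(p, 1.0),
                genes=tuple(sorted(hits)),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of this p in ascending order
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def write_enrichment_tsv(
    records: Iterable[EnrichmentRecord], path: str | Path, group: str = ""
) -> None:
    with open(path, "w") as fh:
        fh.write("ID\tterm\tgene_names\tk\tK\tn\tN\tp\tgroup\n")
        for r in records:
            fh.write(
                f"{r.term_id}\t{r.description}\t{','.join(r.genes)}\t"
                f"{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.6g}\t{group}\n"
            )
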