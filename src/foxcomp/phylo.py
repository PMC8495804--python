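"""Four-taxon (plus outgroup) phylogeny from concatenated ortholog alignments.

Neighbor joining on amino-acid p-distances with pairwise deletion of gapped
columns, nonparametric bootstrap over supermatrix columns, and outgroup
rooting.  On additive matrices NJ recovers the generating topology exactly,
which is what the test fixtures exploit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "Supermatrix",
    "concat_alignment",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "root_at_outgroup",
]

GAP_CHARS = frozenset("-X")


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated per-gene alignments over one shared taxon set."""

    taxa: tuple[str, ...]
    rows: Mapping[str, str]
    partitions: tuple[tuple[str, int, int], ...]  # (gene, start0, end0-exclusive)

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.taxa[0]])


def concat_alignment(gene_alignments: Mapping[str, Mapping[str, str]]) -> Supermatrix:
    """Column-wise concatenation of per-gene alignments with identical taxa."""
    if not gene_alignments:
        raise ValueError("no gene alignments supplied")
    genes = sorted(gene_alignments)
    taxa = tuple(sorted(gene_alignments[genes[0]]))
    rows = {t: [] for t in taxa}
    partitions = []
    offset = 0
    for gene in genes:
        aln = gene_alignments[gene]
        if tuple(sorted(aln)) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValueError(f"gene {gene!r}: taxon set mismatch ({sorted(missing)})")
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene!r}: unequal row lengths")
        width = lengths.pop()
        for t in taxa:
            rows[t].append(aln[t])
        partitions.append((gene, offset, offset + width))
        offset += width
    return Supermatrix(
        taxa=taxa,
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=tuple(partitions),
    )


def p_distance_matrix(
    matrix: Supermatrix, columns: Sequence[int] | None = None
) -> DistanceMatrix:
    """Proportion of differing comparable columns per pair (pairwise deletion)."""
    taxa = matrix.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    idx = range(matrix.n_columns) if columns is None else columns
    arrs = {t: matrix.rows[t] for t in taxa}
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            comparable = diffs = 0
            for c in idx:
                x, y = a[c], b[c]
                if x in GAP_CHARS or y in GAP_CHARS:
                    continue
                comparable += 1
                diffs += x != y
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            dm[i, j] = dm[j, i] = diffs / comparable
    return DistanceMatrix(dm, list(taxa))


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; negative branch lengths clamped to zero."""
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(dist)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def bipartitions(tree: TreeNode, taxa: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial splits of an (un)rooted tree, canonicalised.

    Each internal edge yields the side not containing the alphabetically
    first taxon, so splits compare across rootings.
    """
    full = frozenset(taxa)
    ref = min(full)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = full - clade if ref in clade else clade
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    leaf = tree.find(outgroup)
    return tree.root_at(leaf.parent)


def bootstrap_support(
    matrix: Supermatrix, n_reps: int = 100, seed: int = 0, outgroup: str | None = None
) -> TreeNode:
    """NJ tree on the full supermatrix with bootstrap percentages on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; support for an
    internal edge is the percentage of replicate trees containing its
    bipartition, stored as the internal node name (rounded to int).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full_tree = nj_tree(p_distance_matrix(matrix))
    counts: dict[frozenset[str], int] = {
        bp: 0 for bp in bipartitions(full_tree, matrix.taxa)
    }
    rng = np.random.default_rng(seed)
    n_cols = matrix.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, n_cols)
        try:
            rep = nj_tree(p_distance_matrix(matrix, columns=cols.tolist()))
        except ValueError:  # replicate with no comparable columns for a pair
            continue
        rep_bps = bipartitions(rep, matrix.taxa)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    full = frozenset(matrix.taxa)
    ref = min(full)
    for node in full_tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = clade if ref not in clade else full - clade
        if side in counts:
            node.name = str(round(100.0 * counts[side] / n_reps))
    if outgroup is not None:
        rooted = root_at_outgroup(full_tree, outgroup)
        return rooted
    return full_tree
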