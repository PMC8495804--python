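"""Shared tree-fixture generators for the phylogeny tests."""

import numpy as np
from skbio import DistanceMatrix

from foxcomp.phylo import concat_alignment

TAXA = ("AF", "BF", "RF", "SF", "outgroup")


def random_additive_matrix(rng, taxa=TAXA):
    """Distances generated on a known tree; returns (matrix, true splits).

    Topology is ((AF,BF),(RF,SF),outgroup) with random positive branch
    lengths, so the matrix is exactly additive and NJ must recover it.
    """
    bl = {t: rng.uniform(0.05, 0.5) for t in taxa}
    internal_w = rng.uniform(0.05, 0.5)  # edge above (AF,BF)
    internal_r = rng.uniform(0.05, 0.5)  # edge above (RF,SF)

    def dist(a, b):
        if {a, b} == {"AF", "BF"} or {a, b} == {"RF", "SF"}:
            return bl[a] + bl[b]
        if "outgroup" not in (a, b):
            extra = internal_w + internal_r
        elif {a, b} & {"AF", "BF"}:
            extra = internal_w
        else:
            extra = internal_r
        return bl[a] + bl[b] + extra

    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dist(taxa[i], taxa[j])
    splits = {frozenset({"AF", "BF"}), frozenset({"RF", "SF"})}
    canonical = set()
    full = frozenset(taxa)
    ref = min(full)
    for s in splits:
        canonical.add(s if ref not in s else full - s)
    return DistanceMatrix(m, list(taxa)), canonical


def deep_split_supermatrix(n_blocks=50):
    """Strong, clean phylogenetic signal for the fox topology."""
    rows = {t: [] for t in TAXA}
    for _ in range(n_blocks):
        for t in TAXA:
            rows[t].append("A" if t in ("AF", "BF") else "S")
        for t in TAXA:
            rows[t].append("V" if t in ("RF", "SF") else "T")
        for t in TAXA:
            rows[t].append({"outgroup": "W"}.get(t, "G"))
    return concat_alignment({"g": {t: "".join(v) for t, v in rows.items()}})
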