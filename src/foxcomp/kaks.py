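"""Codon-aware pairwise alignment and Nei–Gojobori (1986) Ka/Ks estimation.

The estimator is the classic counting method: per-codon synonymous /
nonsynonymous site fractions, pathway-averaged difference counts between
codon pairs, Jukes–Cantor correction of both proportions, and the ratio
omega = Ka/Ks.  omega > 1 flags positive selection, omega < 1 purifying.

Site fractions renormalise over non-stop single-nucleotide neighbours and
substitution pathways passing through stop codons are excluded (the MEGA
convention).  Pathways are weighted equally — no transition/transversion
weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqcore import BASES, GENETIC_CODE, STOP_CODONS, CodingSequence, translate

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "codon_aware_align",
    "count_sites",
    "count_differences",
    "jukes_cantor",
    "kaks",
]

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """Two (or more) rows of aligned codon columns for one gene.

    Gaps come in whole-codon units; columns containing a gap or an N in any
    row are flagged uncountable and skipped by the estimator.
    """

    gene_id: str
    ids: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]  # rows[i][j] = codon j of sequence i

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows of {self.gene_id!r} differ in length: {lengths}")
        for row in self.rows:
            for codon in row:
                if codon != GAP_CODON and (len(codon) != 3 or "-" in codon):
                    raise ValueError(f"frameshift codon {codon!r} in {self.gene_id!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def countable_columns(self) -> list[int]:
        """Indices of columns with a valid sense codon (no gap, no N) in every row."""
        out = []
        for j in range(self.n_columns):
            col = [row[j] for row in self.rows]
            if any(c == GAP_CODON or "N" in c or c in STOP_CODONS for c in col):
                continue
            out.append(j)
        return out


@dataclass(frozen=True)
class KaKsResult:
    """NG86 statistics for one aligned pair.

    N, S are sites (averaged over the two sequences); Nd, Sd are
    pathway-averaged difference counts; pN = Nd/N, pS = Sd/S; Ka, Ks the
    Jukes–Cantor-corrected distances.  omega is NaN when undefined (Ks = 0
    or saturation), with the reason in ``selection_flag``.
    """

    gene_id: str
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float
    selection_flag: str  # positive | purifying | neutral | undefined
    note: str = ""


_aligner = PairwiseAligner()
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.mode = "global"
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5


def codon_aware_align(cds_a: CodingSequence, cds_b: CodingSequence) -> CodonAlignment:
    """Align two CDSs at the protein level and back-translate gaps to codons.

    The protein alignment (global, BLOSUM62, affine gaps) guides the
    nucleotide alignment, so gaps always come in whole-codon units and the
    reading frame is preserved.
    """
    for cds in (cds_a, cds_b):
        for i, codon in enumerate(cds.codons()):
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop in {cds.id!r} at codon {i + 1}")
    prot_a, prot_b = translate(cds_a), translate(cds_b)
    aln = _aligner.align(prot_a, prot_b)[0]
    row_a: list[str] = []
    row_b: list[str] = []
    codons_a, codons_b = cds_a.codons(), cds_b.codons()
    for ca, cb in zip(*aln.indices):
        row_a.append(codons_a[ca] if ca >= 0 else GAP_CODON)
        row_b.append(codons_b[cb] if cb >= 0 else GAP_CODON)
    return CodonAlignment(
        gene_id=cds_a.id, ids=(cds_a.id, cds_b.id), rows=(tuple(row_a), tuple(row_b))
    )


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """NG86 site counts for one sense codon: (nonsynonymous, synonymous).

    Per position the synonymous fraction is the share of synonymous changes
    among the non-stop single-nucleotide neighbours; fractions at each
    position sum to 1, so n + s == 3 for every codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = GENETIC_CODE[codon]
    n_total = s_total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour in STOP_CODONS:
                continue
            nonstop += 1
            if GENETIC_CODE[neighbour] == aa:
                syn += 1
        if nonstop == 0:  # cannot happen under the standard code
            continue
        s_total += syn / nonstop
        n_total += 1.0 - syn / nonstop
    return n_total, s_total


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) step counts between codons.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded and the rest weighted equally.
    nd + sd always equals the number of differing positions.
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in difference count")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff):
        current = codon_a
        nd = sd = 0.0
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hits_stop = True
            if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE[current]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        (blocked if hits_stop else paths).append((nd, sd))
    # every sense-codon pair has at least one stop-free pathway under the
    # standard code; the fallback is purely defensive
    usable = paths or blocked
    nd = sum(p[0] for p in usable) / len(usable)
    sd = sum(p[1] for p in usable) / len(usable)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN at saturation (p >= 0.75) rather than raising.
    """
    if p < 0.0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks over the countable columns of a pairwise codon alignment."""
    if len(alignment.rows) != 2:
        raise ValueError("kaks needs a pairwise alignment")
    cols = alignment.countable_columns()
    if not cols:
        raise ValueError(f"no countable columns in {alignment.gene_id!r}")
    row_a, row_b = alignment.rows
    n_a = s_a = n_b = s_b = nd = sd = 0.0
    for j in cols:
        ca, cb = row_a[j], row_b[j]
        na, sa = count_sites(ca)
        nb, sb = count_sites(cb)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = count_differences(ca, cb)
        nd += d_n
        sd += d_s
    N = (n_a + n_b) / 2.0
    S = (s_a + s_b) / 2.0
    pN = nd / N if N > 0 else 0.0
    pS = sd / S if S > 0 else 0.0
    Ka = jukes_cantor(pN)
    Ks = jukes_cantor(pS)
    note = ""
    if math.isnan(Ka) or math.isnan(Ks):
        omega, flag = math.nan, "undefined"
        note = "saturated"
    elif Ks == 0.0:
        omega, flag = math.nan, "undefined"
        note = "Ka>0, Ks=0" if Ka > 0 else "no substitutions"
    else:
        omega = Ka / Ks
        flag = "positive" if omega > 1 else ("purifying" if omega < 1 else "neutral")
    return KaKsResult(
        gene_id=alignment.gene_id,
        N=N, S=S, Nd=nd, Sd=sd, pN=pN, pS=pS, Ka=Ka, Ks=Ks,
        omega=omega, selection_flag=flag, note=note,
    )
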