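"""MISA-style microsatellite (SSR) detection, compound merging and
primer-feasibility screening.

Perfect tandem repeats of 1-6 nt units are reported at their smallest
period, maximal in both directions, with MISA's default minimum repeat
counts (mono 10, di 6, tri 5, tetra 5, penta 5, hexa 5).  Consecutive loci
separated by at most ``max_interruption`` nucleotides form a compound SSR.
Primer feasibility replaces thermodynamic design with window enumeration:
primers of 18-22 nt in the flanks, product length 100-400 bp, ranked by
GC-content proximity to 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .seqcore import NucSequence

__all__ = [
    "SSRThresholds",
    "SSRLocus",
    "PrimerWindowPair",
    "detect_ssrs",
    "merge_compound",
    "primer_feasible",
    "canonical_motif",
    "write_misa_table",
    "summarize_by_unit",
]

MISA_DEFAULTS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat count per unit size plus the compound-merge distance."""

    min_repeats: dict[int, int] = field(default_factory=lambda: dict(MISA_DEFAULTS))
    max_interruption: int = 100

    def __post_init__(self) -> None:
        for unit, thr in self.min_repeats.items():
            if not 1 <= unit <= 6:
                raise ValueError(f"unit size {unit} outside 1-6")
            if thr < 2:
                raise ValueError(f"minimum repeats must be >= 2, got {thr}")


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect tandem repeat; coordinates 1-based inclusive."""

    seq_id: str
    motif: str          # unit as it appears at the locus start
    unit_size: int
    repeats: int
    start: int
    end: int
    compound_id: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_size * self.repeats:
            raise ValueError("locus span does not equal unit_size * repeats")

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)


def canonical_motif(motif: str, *, strand_joint: bool = False) -> str:
    """Lexicographic minimum over rotations; over both strands if requested."""
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    if strand_joint:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(motif))
        rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def _is_primitive(motif: str) -> bool:
    """True when the motif's smallest period equals its length."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def detect_ssrs(
    seq: NucSequence, thresholds: SSRThresholds | None = None
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the thresholds.

    A repeat whose unit is itself periodic (ACAC as 2 x AC) is reported at
    its smallest period only; units containing N are skipped.  Output is in
    coordinate order (start, then unit size).
    """
    thr = thresholds or SSRThresholds()
    s = seq.seq
    n = len(s)
    loci: list[SSRLocus] = []
    for unit, min_rep in sorted(thr.min_repeats.items()):
        p = 0
        # maximal runs of the relation s[x] == s[x + unit]
        while p < n - unit:
            if s[p] == s[p + unit]:
                q = p
                while q < n - unit and s[q] == s[q + unit]:
                    q += 1
                span = q - p + unit  # run covers s[p : q + unit]
                repeats = span // unit
                motif = s[p : p + unit]
                if (
                    repeats >= min_rep
                    and "N" not in motif
                    and _is_primitive(motif)
                ):
                    loci.append(
                        SSRLocus(
                            seq_id=seq.id,
                            motif=motif,
                            unit_size=unit,
                            repeats=repeats,
                            start=p + 1,
                            end=p + unit * repeats,
                        )
                    )
                p = q + 1
            else:
                p += 1
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def merge_compound(loci: list[SSRLocus], max_interruption: int = 100) -> list[SSRLocus]:
    """Assign shared compound ids to runs of nearby loci on one sequence.

    Input must be sorted by (seq_id, start); loci separated by more than
    ``max_interruption`` nt (or alone) keep ``compound_id=None``.
    """
    order = [(l.seq_id, l.start) for l in loci]
    if order != sorted(order):
        raise ValueError("loci must be sorted by (seq_id, start)")
    out: list[SSRLocus] = []
    group: list[SSRLocus] = []
    next_id = 0

    def flush() -> int:
        nonlocal next_id
        if len(group) >= 2:
            for l in group:
                out.append(replace(l, compound_id=next_id))
            next_id += 1
        else:
            out.extend(group)
        group.clear()
        return next_id

    for locus in loci:
        if group and (
            locus.seq_id != group[-1].seq_id
            or locus.start - group[-1].end - 1 > max_interruption
        ):
            flush()
        group.append(locus)
    flush()
    return out


@dataclass(frozen=True)
class PrimerWindowPair:
    """A feasible forward/reverse primer placement around one SSR locus.

    Coordinates are 1-based inclusive on the input sequence; the reverse
    primer is reported as its window on the forward strand.  ``gc_penalty``
    is the summed distance of both windows' GC% from 50.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    product_len: int
    gc_penalty: float


def _gc(s: str) -> float:
    return 100.0 * sum(b in "GC" for b in s) / len(s)


def primer_feasible(
    seq: NucSequence,
    locus: SSRLocus,
    primer_len_range: tuple[int, int] = (18, 22),
    product_range: tuple[int, int] = (100, 400),
    flank_min: int = 0,
    n_pairs: int = 3,
) -> list[PrimerWindowPair]:
    """Up to ``n_pairs`` primer window pairs flanking ``locus``, best first.

    Enumerates all primer windows of the allowed lengths that lie entirely
    in the flanks (at least ``flank_min`` nt clear of the locus) with a
    product length — inclusive of both primers — inside ``product_range``,
    and ranks them by combined GC distance from 50%.  Empty list means
    infeasible.
    """
    if not (1 <= locus.start and locus.end <= len(seq)):
        raise ValueError("locus outside sequence")
    lmin, lmax = primer_len_range
    pmin, pmax = product_range
    s = seq.seq
    left_limit = locus.start - 1 - flank_min  # last usable position on the left
    right_limit = locus.end + 1 + flank_min  # first usable position on the right
    candidates: list[PrimerWindowPair] = []
    for llen in range(lmin, lmax + 1):
        for lstart in range(1, left_limit - llen + 2):
            lend = lstart + llen - 1
            if lend > left_limit:
                break
            for rlen in range(lmin, lmax + 1):
                rstart_min = max(right_limit, lstart + pmin - rlen)
                rstart_max = min(len(s) - rlen + 1, lstart + pmax - rlen)
                for rstart in range(rstart_min, rstart_max + 1):
                    rend = rstart + rlen - 1
                    product = rend - lstart + 1
                    if not pmin <= product <= pmax:
                        continue
                    penalty = abs(_gc(s[lstart - 1 : lend]) - 50.0) + abs(
                        _gc(s[rstart - 1 : rend]) - 50.0
                    )
                    candidates.append(
                        PrimerWindowPair(lstart, lend, rstart, rend, product, penalty)
                    )
    candidates.sort(
        key=lambda c: (c.gc_penalty, c.left_start, c.right_start, c.product_len)
    )
    return candidates[:n_pairs]


def write_misa_table(loci: Iterable[SSRLocus], path: str | Path) -> None:
    """MISA-compatible tab layout: ID, SSR nr., type, SSR, size, start, end."""
    counts: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\tcompound\n")
        for l in loci:
            counts[l.seq_id] = counts.get(l.seq_id, 0) + 1
            ssr_type = ["p1", "p2", "p3", "p4", "p5", "p6"][l.unit_size - 1]
            compound = "" if l.compound_id is None else f"c{l.compound_id}"
            fh.write(
                f"{l.seq_id}\t{counts[l.seq_id]}\t{ssr_type}\t"
                f"({l.motif}){l.repeats}\t{l.end - l.start + 1}\t{l.start}\t{l.end}\t{compound}\n"
            )


def summarize_by_unit(loci: Iterable[SSRLocus]) -> dict[int, int]:
    """Locus counts keyed by unit size (the bar-plot categories)."""
    out: dict[int, int] = {}
    for l in loci:
        out[l.unit_size] = out.get(l.unit_size, 0) + 1
    return out
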