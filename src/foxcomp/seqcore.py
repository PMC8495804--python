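"""Genetic-code arithmetic, FASTA I/O, ORF extraction and the CDS length filter.

Everything downstream (ortholog pairing, Ka/Ks, the mutation screen, the
simulator) builds on the primitives here.  Sequences are plain upper-case
strings over {A, C, G, T, N}; coordinates in every report are 1-based
inclusive; strand is "+" or "-".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUC_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"

#: Standard genetic code: 64 codons -> amino-acid letter, '*' for stop.
#: All taxa handled here are mammals, so only table 1 is used.
GENETIC_CODE: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)
STOP_CODONS: frozenset[str] = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
assert len(GENETIC_CODE) == 64 and len(STOP_CODONS) == 3


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class DuplicateIdError(ValueError):
    """Two records in one FASTA share an id."""


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence (a unigene, a CDS, a fixture read)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains letters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, str(Seq(self.seq).reverse_complement()))


@dataclass(frozen=True)
class CodingSequence:
    """A frame-validated coding sequence.

    ``seq`` excludes the terminal stop codon; ``ends_with_stop`` records
    whether a stop followed it in the source (transcriptome fragments may
    run off the 3' end without one).  Coordinates, when derived from an ORF
    scan, locate the coding portion on the *input* sequence.
    """

    id: str
    seq: str
    frame_validated: bool = True
    ends_with_stop: bool = False
    start: int | None = None  # 1-based inclusive, on the source sequence
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.seq) % 3 != 0:
            raise FrameError(
                f"CDS {self.id!r} length {len(self.seq)} is not a multiple of 3"
            )
        if self.frame_validated:
            for i in range(0, len(self.seq), 3):
                codon = self.seq[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"CDS {self.id!r} has internal stop {codon} at codon {i // 3 + 1}"
                    )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


def translate(seq: str | CodingSequence) -> str:
    """Translate an in-frame coding sequence to protein.

    Stops render as ``*``; any codon containing N renders as ``X`` (such
    codons are excluded from all downstream counting).
    """
    s = seq.seq if isinstance(seq, CodingSequence) else seq
    if len(s) % 3 != 0:
        raise FrameError(f"length {len(s)} is not a multiple of 3")
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


def codon_to_nt_span(codon_index: int) -> tuple[int, int]:
    """Map a 1-based codon index to its 1-based inclusive nucleotide span.

    Codon 79 spans sites 235-237; codon 51 spans 151-153.
    """
    if codon_index < 1:
        raise ValueError(f"codon_index must be >= 1, got {codon_index}")
    return 3 * codon_index - 2, 3 * codon_index


def _orf_candidates(seq: str, require_atg: bool) -> Iterable[tuple[int, int, bool]]:
    """Yield (start0, end0_exclusive, ends_with_stop) ORFs in one forward frame set.

    Scans all three frames of ``seq``.  An ORF runs from a start codon (ATG,
    or any frame position when ``require_atg`` is false: stop-to-stop mode)
    to the next in-frame stop, or to the end of the readable frame.
    """
    n = len(seq)
    for frame in range(3):
        start = None if require_atg else frame
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None and i > start:
                    yield start, i, True
                start = None if require_atg else i + 3
            elif start is None and require_atg and codon == "ATG":
                start = i
        if start is not None:
            last = start + ((n - start) // 3) * 3
            if last > start:
                yield start, last, False


def find_longest_orf(
    unigene: NucSequence, min_len_nt: int = 300, *, require_atg: bool = True
) -> CodingSequence | None:
    """Six-frame scan for the longest ORF, with the transcriptome length filter.

    Returns the longest ORF of coding length >= ``min_len_nt`` (the length
    excludes the terminal stop codon), or None.  The study keeps CDSs of at
    least 300 nt, hence the default.  Ties prefer the forward strand, then
    the lowest start coordinate.  ``require_atg=False`` switches to
    stop-to-stop ORFs for inputs whose 5' ends are truncated.
    """
    if not unigene.seq:
        raise ValueError("empty sequence")
    n = len(unigene)
    best: tuple[int, int, int, str, bool] | None = None  # (-len, strand_rank, start0, ...)
    for strand, s in (("+", unigene.seq), ("-", unigene.reverse_complement().seq)):
        for a, b, stopped in _orf_candidates(s, require_atg):
            length = b - a
            key = (-length, 0 if strand == "+" else 1, a)
            if best is None or key < best[:3]:
                best = (*key, strand, stopped)
    if best is None:
        return None
    neg_len, _, a, strand, stopped = best
    length = -neg_len
    if length < min_len_nt:
        return None
    if strand == "+":
        start1, end1 = a + 1, a + length
        sub = unigene.seq[a : a + length]
    else:  # map reverse-strand coordinates back onto the input
        start1, end1 = n - (a + length) + 1, n - a
        sub = unigene.reverse_complement().seq[a : a + length]
    return CodingSequence(
        unigene.id, sub, ends_with_stop=stopped, start=start1, end=end1, strand=strand
    )


def read_fasta(path: str | Path) -> dict[str, NucSequence]:
    """Read a (wrapped or unwrapped) FASTA into an id-keyed dict.

    Lowercase letters are uppercased; duplicate ids raise naming the id;
    an empty file yields an empty dict with a warning.
    """
    out: dict[str, NucSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = NucSequence(rec.id, str(rec.seq).upper())
    if not out:
        logger.warning("FASTA file %s contained no records", path)
    return out


def write_fasta(seqs: Iterable[NucSequence | CodingSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA (for RBH on externally translated sets)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out
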