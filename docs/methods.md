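# Methods

## Scope and design

`foxcomp` implements a comparative molecular-evolution workflow for two
wild/farmed fox pairs — arctic fox (AF) vs. blue fox (BF) and red fox (RF)
vs. silver fox (SF) — from assembled transcripts to selection statistics,
lineage-exclusive substitutions, microsatellite markers and a phylogeny.
Several stages are deliberate, documented stand-ins for heavyweight
external tools, chosen so the same statistics are computed without external
binaries or databases:

- a six-frame longest-ORF scan stands in for HMM/BLAST-based CDS recovery;
- reciprocal best hit (RBH) stands in for all-vs-all BLAST + MCL ortholog
  clustering — single-copy orthologs, the only kind this workflow keeps,
  are exactly the RBH-recoverable ones;
- the Nei–Gojobori (1986) counting estimator stands in for ML codon models;
  it estimates the identical ω statistic deterministically, though its
  values will diverge from codeml's on real, deeply diverged data;
- neighbor joining on p-distances stands in for parsimony/ML tree search;
  it is deterministic and exactly recoverable on additive matrices;
- GC-content window scoring stands in for primer thermodynamics;
- a single hypergeometric upper-tail test stands in for the several
  enrichment tools whose differences are database-driven.

## CDS extraction

ORFs are sought in all six frames; an ORF runs from ATG to the next
in-frame stop or to the sequence end (transcriptome fragments may lack a
stop; the `ends_with_stop` flag records which). The reported coding length
excludes the terminal stop codon, and the length filter keeps CDSs of
**≥ 300 nt** (the boundary is configurable; "longer than 300" is read
inclusively). Ties between equally long ORFs prefer the forward strand,
then the lowest start. A configuration flag admits stop-to-stop ORFs for
5'-truncated inputs; it is off by default. Codons containing N translate to
`X` and are excluded from all downstream counting.

## NG86 Ka/Ks

For each codon, each position's synonymous site fraction is the share of
synonymous changes among its non-stop single-nucleotide neighbours
(renormalising over non-stop neighbours, the MEGA convention), so every
codon contributes exactly 3 sites. Between two codons, substitution
pathways over all orderings of the differing positions are enumerated;
pathways through stop codons are excluded and the remainder weighted
equally — no transition/transversion weighting. Under the standard code
every sense-codon pair retains at least one stop-free pathway (verified
exhaustively in the tests); a defensive fallback averages over all pathways
if none survives. Sites are averaged over the two sequences, differences
summed over countable columns, and both proportions Jukes–Cantor corrected:
d = −(3/4)·ln(1 − 4p/3), undefined (NaN) at p ≥ 0.75. ω = Ka/Ks when
Ks > 0; Ks = 0 yields an undefined ω with the reason recorded (`Ka>0,
Ks=0` genes are listed, not ranked). Alignment is protein-guided: proteins
are aligned globally (BLOSUM62, gap open −10, extend −0.5) and gaps
back-translated as whole-codon units, so the frame is never broken; columns
with a gap or N in either row are excluded pairwise.

## Lineage-exclusive screen

A residue column qualifies when a candidate focal group — both farmed
foxes, one farmed fox alone, or the wild pair — shares a residue absent
from every other taxon, and the non-focal taxa are invariant. Candidates
are evaluated in that order; gapped, stop-containing and ambiguous (`X`)
columns are skipped. Conservation is strict by default; a tolerance
parameter k (default 0) admits up to k non-focal taxa deviating from their
majority residue, the focal residue itself never being admissible. Both
directions are reported — a residue exclusive to the wild pair is
biologically a farmed-side change viewed from the other direction, and the
wild-exclusive W→R case in the worked examples would be missed by a
farmed-only screen. The reported nucleotide site is the single position at
which the focal codon differs from the majority background codon, numbered
1-based from the CDS start (codon 79 site 235, codon 51 site 153, codon 176
site 527); multi-nucleotide codon differences report the first differing
position and carry a flag. The screen is monotone in the panel: adding taxa
can only remove flagged sites, never add them.

One inconsistency in the worked material is resolved as follows: the L→Q
change at CDS site 527 requires T→A at the codon's second position, and is
attributed to the silver fox; fixtures therefore plant CTA→CAA at codon 176
with SF as the focal taxon.

## SSR detection

Maximal perfect tandem repeats of 1–6 nt units are found as maximal runs of
the relation s[x] = s[x+u]; a run of span L yields ⌊L/u⌋ repeats,
left-aligned. Motifs that are themselves periodic (ACAC as 2×AC) are
suppressed, so every locus is reported at its smallest period only.
Default minimum repeat counts are the MISA defaults — mono 10, di 6, tri 5,
tetra 5, penta 5, hexa 5 — configurable per unit size. Only perfect repeats
are detected. Consecutive loci separated by ≤ 100 nt (configurable) share a
compound id. Motifs are canonicalised for reporting as the lexicographic
minimum over rotations; joint canonicalisation over both strands is
available behind a flag, off by default. Primer feasibility enumerates all
18–22 nt flank windows whose product (inclusive of primers) is 100–400 bp
and returns up to three pairs ranked by summed GC% distance from 50 —
placement feasibility, not thermodynamic design.

## Synthetic data

The generator emulates the study conditions rather than the sequencing:
per-taxon unigene sets containing ORFs of at least 300 nt, ortholog
quartets under controlled ω, an invariant mammalian panel with planted
group-exclusive substitutions, and SSR-bearing unigenes, each with a truth
table.

Substitution uses an acceptance-ratio scheme rather than a full codon rate
matrix (GY94): each event proposes a uniform single-nucleotide change at a
uniform non-start-codon site, rejects stop-creating changes, and accepts
synonymous proposals with probability min(1, 1/ω) and nonsynonymous ones
with min(1, ω). The realised nonsynonymous:synonymous substitution ratio
then scales with ω relative to the neutral site ratio — which is the
quantity a counting estimator measures — while making no claim to match ML
codon-model likelihoods. The start codon is held fixed so ORF recovery is
exact. Tips evolve independently from their (group) ancestor; within a
pair, divergence is the sum of two independent lineages, and a shared
group branch plants the ((AF,BF),(RF,SF)) topology with a more deeply
diverged outgroup (4× the per-lineage events). Base composition is uniform
over non-stop codons.

Default study scale is 20 genes × 200 codons with 60 substitution events
per lineage, ω = 0.2 for background genes and ω = 3 for 3 positively
selected ones — large enough for every stage to have signal, small enough
that the full pipeline runs in about a second. Calibration checks use 500
codons and 200 events per lineage over 50 replicates, where the mean
estimate under ω = 0.2 falls in [0.14, 0.26] and the median under ω = 3 is
close to 3. SSR fixtures verify, at generation time, that detection of the
planted locus returns exactly the planted coordinates (flank adjacency can
otherwise extend a tract), and re-draw the background when it does not.

What the generator does **not** emulate: read-level error, assembly
artefacts and fragmentation, paralogy, alignment uncertainty from real
indel processes, rate heterogeneity across sites and lineages, and
base-composition bias. Passing the suite therefore demonstrates the
correctness of the statistics and the recoverability of planted signal, not
performance on raw sequencing data.

## Phylogeny

Amino-acid p-distances with pairwise deletion of gapped columns feed
canonical neighbor joining; negative NJ branch lengths are clamped to zero.
Bootstrap resamples supermatrix columns with replacement, rebuilds the
tree, and reports the percentage of replicates containing each internal
edge's bipartition, attached to the full-data tree; replicates in which
some pair loses all comparable columns are skipped. Rooting is at the
designated outgroup when present.

## Enrichment

The upper-tail hypergeometric probability P(X ≥ k) for k study hits in a
term of size K, study size n, population N; the default background is every
gene in the supplied annotation. Raw p-values are reported unfiltered;
Benjamini–Hochberg step-up adjustment is available as an option. No GO
graph propagation or pathway topology.

## Pipeline determinism

All stages derive randomness from the single run seed; outputs contain no
timestamps and no filesystem-order dependence, so reruns with the same seed
and configuration are byte-identical. The run log records the package
version, the seed and a hash of the scientific configuration (output paths
excluded).

## Known limitations

- NG86 underestimates ω at high divergence (no multiple-hit modelling
  beyond Jukes–Cantor, equal pathway weights); comparisons with ML methods
  on real data will differ, particularly for genes with few synonymous
  substitutions.
- RBH cannot separate recent in-paralogs; ties are dropped conservatively
  rather than resolved.
- The ORF extractor assumes the longest ATG-initiated frame is the coding
  one; non-ATG starts and frameshifted assemblies are out of scope.
- Perfect repeats only; imperfect microsatellites are invisible to the
  scanner.
- Bootstrap supports on very short supermatrices are granular (percentages
  of few replicates).
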