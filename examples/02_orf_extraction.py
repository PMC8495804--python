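"""Extract the longest ORF from a transcriptome-style unigene and apply the
300-nt CDS length filter used for all downstream analysis."""

from foxcomp import NucSequence, find_longest_orf, translate
from foxcomp.simulate import generate_ancestral_cds

coding = generate_ancestral_cds(120, seed=8).seq  # 360 nt of coding sequence
unigene = NucSequence("unigene_1", "CCTTCCTT" + coding + "TAA" + "CCTTCC")

orf = find_longest_orf(unigene, min_len_nt=300)
print(f"ORF on strand {orf.strand}, sites {orf.start}-{orf.end}, {len(orf)} nt")
print(f"protein starts: {translate(orf)[:25]}...")

short = NucSequence("unigene_2", "CC" + coding[:297] + "TAA")
print("297-nt ORF kept at min 300?", find_longest_orf(short, 300) is not None)
# Only coding sequences of >= 300 nt survive, mirroring the study's filter.
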