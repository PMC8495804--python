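"""Generate a small synthetic study: ortholog quartets for the two
wild/farmed fox pairs, conservation panels with the three worked
substitutions, and SSR-bearing unigenes — with truth tables for scoring."""

from pathlib import Path

from foxcomp.simulate import SimConfig, generate_study

out = Path("scratch/example_study")
config = SimConfig(n_genes=10, n_codons=150, n_positive=2, seed=42)
files = generate_study(config, out)

print(f"Wrote {len(files)} files to {out}/")
print("Per-gene true omega values (purifying 0.2, positive 3):")
print((out / "truth_omega.tsv").read_text())
print("Planted group-exclusive substitutions (CDS nucleotide sites):")
print((out / "truth_plants.tsv").read_text())
# The truth tables let every downstream stage be scored automatically:
# the screen must find exactly these sites, Ka/Ks must recover these omegas.
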