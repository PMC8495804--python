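"""Detect microsatellites, merge compound SSRs, and check primer feasibility."""

import numpy as np

from foxcomp import NucSequence, SSRThresholds, detect_ssrs, merge_compound
from foxcomp.simulate import plant_ssr
from foxcomp.ssr import primer_feasible

rng = np.random.default_rng(1)
background = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
seq = plant_ssr(NucSequence("u1", background), "AC", 7, 151)
seq = plant_ssr(seq, "AAG", 6, 205)  # 40 nt downstream: a compound partner

loci = merge_compound(detect_ssrs(seq, SSRThresholds()), max_interruption=100)
for l in loci:
    tag = f"compound c{l.compound_id}" if l.compound_id is not None else "single"
    print(f"({l.motif}){l.repeats} at {l.start}-{l.end} [{tag}]")

windows = primer_feasible(seq, loci[0])
if windows:
    w = windows[0]
    print(
        f"best primer windows: {w.left_start}-{w.left_end} / "
        f"{w.right_start}-{w.right_end}, product {w.product_len} bp"
    )
# Loci within 100 nt of each other share a compound id; primer windows of
# 18-22 nt are ranked by GC% closeness to 50 with products of 100-400 bp.
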