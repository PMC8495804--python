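import numpy as np
import pytest

from foxcomp.seqcore import CodingSequence
from foxcomp.simulate import FIGURE_PLANTS, generate_ancestral_cds


@pytest.fixture(scope="session")
def ancestor_500():
    return generate_ancestral_cds(500, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def figure_panels():
    """One 13-taxon codon panel per worked gene, each with its single plant."""
    from foxcomp.simulate import generate_panel

    panels = {}
    for plant in FIGURE_PLANTS:
        n_codons = max(200, plant.codon_index)
        base = CodingSequence(
            plant.gene_id, generate_ancestral_cds(n_codons, seed=101).seq
        )
        panels[plant.gene_id] = (plant, generate_panel(base, [plant]))
    return panels
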