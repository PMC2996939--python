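"""Shared fixtures: a hand-built two-gene genome and a small simulated run."""

import pytest

from phosnp.core_io import GeneModel
from phosnp.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_plus_gene():
    """'+'-strand gene, 2 exons, CDS ATG TCT AGA GGA TAA (M S R G *)."""
    #                 genomic:  1-6           101-109
    # CDS = ATGTCT + AGAGGATAA
    genome = {"chrA": "ATGTCT" + "G" * 94 + "AGAGGATAA" + "C" * 20}
    model = GeneModel("g_plus", "chrA", "+", ((1, 6), (101, 109)))
    return genome, model, "MSRG"


@pytest.fixture(scope="session")
def toy_minus_gene():
    """'-'-strand single-exon gene encoding M S R G * on the reverse strand."""
    cds = "ATGTCTAGAGGATAA"
    rc = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]  # genomic sense
    genome = {"chrB": "TT" + rc + "AA"}
    model = GeneModel("g_minus", "chrB", "-", ((3, 3 + len(cds) - 1),))
    return genome, model, "MSRG"


@pytest.fixture(scope="session")
def sim_small():
    """A deterministic 60-protein simulated dataset with SNPs."""
    config = SimulationConfig(n_proteins=60, seed=11)
    return simulate(config)
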