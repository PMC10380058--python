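import numpy as np
import pytest

from tgskit.genotypes import GenotypeMatrix
from tgskit.panel import Panel, SNPPanelEntry, bundled_panel


@pytest.fixture(scope="session")
def panel39() -> Panel:
    return bundled_panel()


@pytest.fixture()
def tiny_panel() -> Panel:
    """Four loci with varied alleles and betas spanning the bundled range."""
    return Panel(
        entries=(
            SNPPanelEntry(rsid="rs1", gene="G1", beta=0.055,
                          earlier_allele="A", later_allele="G",
                          ref_freqs={"X": 0.1, "Y": 0.2}),
            SNPPanelEntry(rsid="rs2", gene="G2", beta=0.019,
                          earlier_allele="C", later_allele="T",
                          ref_freqs={"X": 0.4, "Y": 0.3}),
            SNPPanelEntry(rsid="rs3", gene="G3", beta=0.030,
                          earlier_allele="T", later_allele="A",
                          ref_freqs={"X": 0.25, "Y": 0.25}),
            SNPPanelEntry(rsid="rs4", gene="G4", beta=0.022,
                          earlier_allele="G", later_allele="C",
                          ref_freqs={"X": 0.5, "Y": 0.45}),
        ),
        name="tiny4",
    )


@pytest.fixture()
def tiny_matrix(tiny_panel) -> GenotypeMatrix:
    """Three samples x four loci, one missing call, one het per row."""
    calls = np.array([
        ["AA", "CT", "TT", "GG"],
        ["AG", "TT", "AA", "CC"],
        ["GG", "CC", "",   "GC"],
    ], dtype="U2")
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        locus_ids=["rs1", "rs2", "rs3", "rs4"],
        calls=calls,
    )
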