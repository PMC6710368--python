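import pytest

from nnrr_regulon.genome import Gene, GenomeAnnotation
from nnrr_regulon.synthetic import make_scenario


@pytest.fixture(scope="session")
def scenario():
    """One seeded end-to-end synthetic study shared across tests."""
    return make_scenario(seed=7)


@pytest.fixture()
def toy_annotation():
    """Three-gene forward-strand toy replicon: gaps of 50 and 300 bp."""
    genes = [
        Gene("g1", 1001, 1900, "+"),
        Gene("g2", 1951, 2850, "+"),   # gap to g1: 50
        Gene("g3", 3151, 4050, "+"),   # gap to g2: 300
    ]
    return GenomeAnnotation("toy", 5000, genes)


def polya_genome_with(segment: str, at: int, length: int = 3000) -> str:
    """Poly-A background (no chance motif hits) with *segment* written in."""
    g = ["A"] * length
    g[at - 1:at - 1 + len(segment)] = list(segment)
    return "".join(g)
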