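import numpy as np
import pytest

from acedhs.hky import Tree
from acedhs.intervals import GenomicInterval, GeneRecord
from acedhs.motifs import PWM
from acedhs.simulate import DEFAULT_TREE, SimulationConfig, simulate_alignment


@pytest.fixture(scope="session")
def default_tree() -> Tree:
    return Tree.from_newick(DEFAULT_TREE)


@pytest.fixture(scope="session")
def neutral_alignment():
    """A 2 kb neutral ortholog alignment on the default tree."""
    return simulate_alignment(
        SimulationConfig(seed=12, element_length=2000), "neutral_2k"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_genes() -> list[GeneRecord]:
    """Two genes on chrS: one forward with two exons, one reverse."""
    g1 = GeneRecord(
        "geneA",
        GenomicInterval("chrS", 10_000, 20_000, id="geneA"),
        "+",
        exons=[
            GenomicInterval("chrS", 10_000, 10_500),
            GenomicInterval("chrS", 19_000, 20_000),
        ],
    )
    g2 = GeneRecord(
        "geneB",
        GenomicInterval("chrS", 40_000, 48_000, id="geneB"),
        "-",
        exons=[GenomicInterval("chrS", 47_000, 48_000)],
    )
    return [g1, g2]


@pytest.fixture(scope="session")
def sharp_pwm() -> PWM:
    """A near-deterministic 6-bp motif (consensus TGACGT)."""
    counts = np.array(
        [
            [1, 1, 48, 1, 1, 1],
            [1, 1, 1, 48, 1, 1],
            [1, 48, 1, 1, 48, 1],
            [48, 1, 1, 1, 1, 48],
        ],
        dtype=float,
    )
    return PWM.from_counts("TOY6", counts)


def random_intervals(rng, n, chrom="chrS", max_pos=10_000, max_len=300):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, id=f"iv{i}"))
    return out
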