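import numpy as np
import pytest

from sigstrat import TranscriptAnnotation, synthetic_signatures
from sigstrat.schemas import BASES


@pytest.fixture(scope="session")
def tiny_genome():
    """Deterministic 1 kb contig with one gene per strand.

    Gene layout: [100, 400) on '+', [500, 800) on '-', and an antisense
    stretch [250, 300) on '-' overlapping the first gene (B category).
    """
    rng = np.random.default_rng(12345)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=1000)])
    genome = {"chr1": seq}
    annotation = TranscriptAnnotation([
        ("chr1", 100, 400, "+"),
        ("chr1", 500, 800, "-"),
        ("chr1", 250, 300, "-"),
    ])
    return genome, annotation


@pytest.fixture(scope="session")
def pool96():
    return synthetic_signatures(4, "SBS96", seed=2024)


@pytest.fixture(scope="session")
def pool384():
    return synthetic_signatures(4, "SBS384", seed=2024)
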