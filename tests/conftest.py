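import random

import pytest

from gbskit.enzymes import BUILTIN_ENZYMES
from gbskit.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def apeki():
    return BUILTIN_ENZYMES["ApeKI"]


@pytest.fixture(scope="session")
def msei():
    return BUILTIN_ENZYMES["MseI"]


@pytest.fixture(scope="session")
def psti():
    return BUILTIN_ENZYMES["PstI"]


def random_sequence(length: int, seed: int, gc: float = 0.5) -> str:
    rng = random.Random(seed)
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=length))


@pytest.fixture(scope="session")
def small_truth():
    """Shared error-free truth set: 8 samples, 60 SNPs, mean locus depth ~5."""
    cfg = SimConfig(
        seed=1234,
        n_contigs=2,
        contig_length=20_000,
        n_snps=60,
        het_fraction=0.0,
        hom_ref_fraction=0.6,
        hom_alt_fraction=0.4,
        mean_depth=10.0,
    )
    return simulate_experiment(cfg)
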