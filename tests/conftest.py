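import numpy as np
import pytest

from coldbias import SimulationParams, simulate_pairs
from coldbias.ortholog_pairing import CodonAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small biased dataset shared by pipeline-level tests."""
    params = SimulationParams(
        n_genes=8, codons_per_gene=120, kappa_gc=2.0,
        syn_rate=0.08, nonsyn_rate=0.04, coil_gain_bias=2.0,
        n_decoys=3, seed=42,
    )
    return params, simulate_pairs(params)


def random_codon_alignment(rng, n_codons=10, allow_gaps=False):
    """Draw a random codon alignment (possibly with stops and gaps)."""
    from coldbias.codon_core import STANDARD_CODE

    all_codons = sorted(STANDARD_CODE.table)
    columns = []
    for _ in range(n_codons):
        codon_a = all_codons[rng.integers(0, 64)]
        if rng.random() < 0.5:
            codon_b = codon_a
        else:
            codon_b = all_codons[rng.integers(0, 64)]
        if allow_gaps and rng.random() < 0.1:
            if rng.random() < 0.5:
                codon_a = None
            else:
                codon_b = None
        columns.append((codon_a, codon_b))
    return CodonAlignment(id_a="a", id_b="b", columns=columns)
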