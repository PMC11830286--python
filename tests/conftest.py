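import numpy as np
import pytest

from fragid import align, fragsim


@pytest.fixture(scope="session")
def blosum():
    return align.default_matrix()


@pytest.fixture(scope="session")
def reference():
    """A 234-residue synthetic target protein."""
    return fragsim.synthetic_reference(234, seed=11)


@pytest.fixture(scope="session")
def standard_db(reference):
    """The benchmark database: target + paralog + 10 labelled homologs +
    50 random decoys (uniform background)."""
    return fragsim.simulate_proteome(
        n_decoys=50,
        length_range=(200, 400),
        target={"sequence": reference},
        paralog_divergence=0.3,
        seed=5,
        n_homologs=10,
        homolog_divergence=0.1,
    )


@pytest.fixture(scope="session")
def bench_db(reference):
    """The sweep database: only unambiguous true records (target + 10
    labelled homologs) among 50 decoys, no paralog.  The paralog confounder
    is measured separately so that the accuracy sweep isolates resolution
    dependence."""
    return fragsim.simulate_proteome(
        n_decoys=50,
        length_range=(200, 400),
        target={"sequence": reference},
        seed=5,
        include_paralog=False,
        n_homologs=10,
        homolog_divergence=0.1,
    )


@pytest.fixture(scope="session")
def decoy_only_db(reference):
    """Target + decoys, no paralog: the zero-noise end-to-end setting."""
    return fragsim.simulate_proteome(
        n_decoys=200,
        length_range=(200, 400),
        target={"sequence": reference},
        seed=5,
        include_paralog=False,
    )


def random_protein(rng: np.random.Generator, length: int) -> str:
    from fragid.alphabet import AA

    return "".join(AA[i] for i in rng.integers(0, 20, size=length))
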