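import numpy as np
import pytest

from peptinfer.io_encoding import (
    PeptideObservation,
    ProteinRecord,
    ProteomeLayout,
    build_encoding,
)
from peptinfer.cnn import CNNConfig, build_model

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_instance(rng, n_proteins=5, length_range=(70, 140), n_peptides=8,
                    pep_length_range=(6, 14)):
    """A small random problem: proteins plus peptides cut from them.

    Every peptide is a substring of at least one protein, so candidate
    selection keeps everything.
    """
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(*length_range))
        proteins.append(
            ProteinRecord(f"P{i:03d}", "".join(rng.choice(AA, size=length)))
        )
    peptides = []
    seen = set()
    while len(peptides) < n_peptides:
        src = proteins[int(rng.integers(n_proteins))]
        plen = int(rng.integers(*pep_length_range))
        if plen >= len(src.sequence):
            continue
        start = int(rng.integers(len(src.sequence) - plen))
        seq = src.sequence[start : start + plen]
        if seq in seen:
            continue
        seen.add(seq)
        peptides.append(PeptideObservation(seq, float(rng.uniform(0.05, 1.0))))
    from peptinfer.io_encoding import select_candidates

    layout, unmatched = select_candidates(proteins, peptides)
    assert not unmatched  # peptides are substrings by construction
    encoding = build_encoding(layout, peptides)
    return layout, encoding


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_problem(rng):
    """Layout + encoding + an (untrained) seeded model on a small instance."""
    layout, encoding = random_instance(rng)
    config = CNNConfig(seed=7, epochs=2, batch_size=4)
    model = build_model(config, layout, seed=7)
    return model, encoding


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic recovery problem used across deeper tests:
    60 proteins of 200-400 residues, 20 truly present, detection 0.5,
    true-peptide probabilities in [0.9, 1], 30 noise peptides in [0, 0.3]."""
    from peptinfer.synthetic import SimulationConfig, generate_sample

    config = SimulationConfig(seed=1)
    return config, generate_sample(config)
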