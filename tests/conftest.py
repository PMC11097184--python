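import numpy as np
import pytest

import molmask as mm


@pytest.fixture(scope="session")
def corpus150():
    """Imbalanced synthetic corpus, 150 molecules, fixed seed."""
    return mm.generate_corpus(mm.fixtures.imbalanced_corpus_spec(150, seed=3))


@pytest.fixture(scope="session")
def corpus500():
    return mm.generate_corpus(mm.fixtures.imbalanced_corpus_spec(500, seed=7))


@pytest.fixture(scope="session")
def labeled_dataset(corpus150):
    """Two binary tasks (contains N / contains O) with 10% missing labels."""
    labels = np.array(
        [
            [
                float(any(a[0] == "N" for a in m.atoms)),
                float(any(a[0] == "O" for a in m.atoms)),
            ]
            for m in corpus150
        ]
    )
    rng = np.random.default_rng(0)
    labels[rng.random(labels.shape) < 0.1] = np.nan
    return corpus150, labels


@pytest.fixture(scope="session")
def ten_scaffold_smiles():
    """Ten molecules with ten distinct Bemis-Murcko scaffolds."""
    return [
        "c1ccccc1C",          # benzene
        "c1ccncc1C",          # pyridine
        "C1CCCCC1C",          # cyclohexane
        "c1ccc2ccccc2c1",     # naphthalene
        "c1ccoc1C",           # furan
        "c1ccsc1C",           # thiophene
        "c1cc[nH]c1C",        # pyrrole
        "C1CCCC1C",           # cyclopentane
        "C1CCNCC1C",          # piperidine
        "C1COCCN1C",          # morpholine
    ]
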