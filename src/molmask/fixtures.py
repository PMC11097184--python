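"""Packaged worked examples: stand-in molecules and the default corpus spec.

The two stand-in molecules are synthetic fixed literals (not drawn from any
deposited data set) reproducing the qualitative atom-composition patterns
the weighted-masking analysis argues from:

* ``mol1_standin`` — a phenyl-containing molecule with exactly one fluorine,
  whose masking removes a semantically load-bearing trace atom;
* ``mol2_standin`` — a phenyl- and carbonyl-containing molecule where
  chlorine, globally a trace element, outnumbers both oxygen and nitrogen
  within the molecule.

``load_expected_values`` exposes the frozen expected-value table shipped
with the test fixtures; every entry carries a provenance tag (PAPER, TRIVIAL
or DERIVED) and, for DERIVED values, the oracle that produced them.
"""

from __future__ import annotations

import csv
from importlib import resources

from .molio import CorpusSpec, MolGraph, parse_smiles

#: synthetic stand-in: phenyl ring bearing an acetamido group and one fluorine
MOL1_STANDIN_SMILES = "CC(=O)Nc1ccc(F)cc1"
#: synthetic stand-in: trichlorophenyl acetamide — chlorine outnumbers O and N
MOL2_STANDIN_SMILES = "CC(=O)Nc1ccc(Cl)c(Cl)c1Cl"


def mol1_standin() -> MolGraph:
    """Phenyl-containing stand-in molecule with exactly one fluorine atom."""
    return parse_smiles(MOL1_STANDIN_SMILES, name="mol1_standin")


def mol2_standin() -> MolGraph:
    """Chlorine-heavy stand-in: phenyl + carbonyl, n_Cl > n_O and n_Cl > n_N."""
    return parse_smiles(MOL2_STANDIN_SMILES, name="mol2_standin")


def imbalanced_corpus_spec(n_molecules: int = 500, seed: int = 0) -> CorpusSpec:
    """Default corpus spec emulating a drug-like library's atom imbalance.

    Target global frequencies: carbon 0.74, oxygen 0.12, nitrogen 0.10
    (C+O+N = 0.96), trace elements S/F/Cl/Br 0.01 each (total 0.04).
    """
    return CorpusSpec(
        n_molecules=n_molecules,
        type_distribution={
            "C": 0.74,
            "O": 0.12,
            "N": 0.10,
            "S": 0.01,
            "F": 0.01,
            "Cl": 0.01,
            "Br": 0.01,
        },
        trace_elements=frozenset({"S", "F", "Cl", "Br"}),
        seed=seed,
    )


VALID_TAGS = {"PAPER", "TRIVIAL", "DERIVED"}


def load_expected_values() -> list:
    """Load the tagged expected-values table shipped with the package.

    Rows have fields (operation, inputs, expected, tag, oracle); the tag is
    one of PAPER / TRIVIAL / DERIVED and DERIVED rows name their oracle.
    """
    text = resources.files("molmask").joinpath("data/expected_values.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    for row in rows:
        if row["tag"] not in VALID_TAGS:
            raise ValueError(f"invalid provenance tag {row['tag']!r}")
        if row["tag"] == "DERIVED" and not row["oracle"].strip():
            raise ValueError(f"DERIVED row missing oracle: {row}")
    return rows
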