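"""Shared fixtures: handcrafted toy genes and small simulated screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crisprtile import GeneModel, SimulationConfig, simulate_gene, design_library

# one unambiguous codon per amino acid, for building genes with a chosen
# protein sequence in tests
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def gene_for(protein: str, gene_id: str = "TOY") -> GeneModel:
    """A gene model whose protein sequence is exactly ``protein``."""
    cds = "".join(CODON[a] for a in protein) + "TAA"
    return GeneModel(gene_id, cds, protein)


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Deterministic 40-residue gene for placement tests."""
    return simulate_gene(n_residues=40, rng=np.random.default_rng(11),
                         gene_id="TOY40")


@pytest.fixture(scope="session")
def sim_gene() -> GeneModel:
    return simulate_gene(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def sim_library(sim_gene):
    lib, act = design_library(sim_gene, SimulationConfig(seed=5))
    return lib, act


def lfc_table_from(values: dict[str, tuple[str, float]]) -> pd.DataFrame:
    """Minimal LFC table: {sgrna_id: (category, lfc_mean)}."""
    df = pd.DataFrame(
        {
            "category": [v[0] for v in values.values()],
            "lfc_mean": [v[1] for v in values.values()],
        },
        index=pd.Index(list(values), name="sgrna_id"),
    )
    df["residues"] = ""
    df["filtered"] = False
    df["filter_reason"] = ""
    return df
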