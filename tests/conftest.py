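"""Shared fixtures: codon table, toy sequences, and a small synthetic dataset."""

import numpy as np
import pytest

from codonmod import CodingSequence, GeneratorConfig, build_codon_table, generate

# Synthetic "toy fluorophore" CDS: a hand-designed stand-in for a real
# fluorescent-protein gene, assembled codon by codon so its queuosine-family
# (NAY) census is known by construction.  All NAY codons start C-ending.
TOY_FLUOROPHORE_CODONS = [
    "ATG", "GTG", "AGC", "AAG", "GGC", "GAG", "GAG", "CTG", "TTC", "ACC",
    "AAC", "GTG", "CCC", "ATC", "CTG", "GTG", "GAC", "CTG", "GAC", "GGC",
    "CAC", "AAG", "TTC", "AGC", "GTG", "TCC", "GGC", "TAC", "GGC", "GAG",
    "AAC", "TGC", "TTC", "GCC", "CGC", "TAC", "CCC", "GAC", "CAC", "ATG",
    "AAC", "CAG", "CAC", "GAC", "TTC", "TTC", "AAG", "TAC", "GCC", "ATG",
    "CCC", "GAA", "GGC", "TAC", "GTC", "CAG", "GAG", "CGC", "ACC", "ATC",
]
TOY_NAY_CENSUS = {"AAC": 3, "GAC": 4, "CAC": 3, "TAC": 4}  # all C-ending


@pytest.fixture(scope="session")
def table():
    return build_codon_table("DNA")


@pytest.fixture(scope="session")
def toy_fluorophore():
    return CodingSequence("toy_fluorophore", "".join(TOY_FLUOROPHORE_CODONS) + "TAA")


@pytest.fixture(scope="session")
def small_dataset():
    """Down-scaled default-structure dataset for fast integration tests."""
    config = GeneratorConfig(
        n_genes=400, gene_length=150, footprints_per_tissue=20_000, min_gene_set=50
    )
    return generate(config, seed=7)


def random_cds(rng: np.random.Generator, table, n_codons: int = 300) -> CodingSequence:
    """Random in-frame CDS over sense codons with a terminal STOP."""
    sense = np.array(table.sense_codons)
    body = "".join(rng.choice(sense, size=n_codons))
    return CodingSequence(f"rand{rng.integers(1 << 30)}", body + "TAA")
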