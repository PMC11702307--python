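"""Shared fixtures: a synthetic LYNX2-like gene model and parameter sets."""

import numpy as np
import pytest

from lynxkit import bell_evans as be
from lynxkit import variant_annotation as va

# Codons excluding stops, used to build deterministic synthetic CDSs.
_SAFE_CODONS = [
    "GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTG",
    "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT",
]


def make_cds(n_codons: int = 90, seed: int = 11, codon_overrides: dict | None = None) -> str:
    """Deterministic synthetic CDS: ATG start, no internal stops.

    ``codon_overrides`` maps 1-based codon index -> codon string.
    """
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n_codons - 1)
    ]
    for idx, codon in (codon_overrides or {}).items():
        codons[idx - 1] = codon
    return "".join(codons)


@pytest.fixture(scope="session")
def lynx2_like_model() -> va.GeneModel:
    """90-codon gene model with a 22-residue signal peptide and Gln at codon 61."""
    cds = make_cds(90, codon_overrides={61: "CAG"})
    return va.GeneModel(cds, signal_peptide_length=22)


@pytest.fixture(scope="session")
def wt_params() -> be.BellEvansParams:
    """Wild-type kinetics: 1,470 s zero-force lifetime, 0.5 nm barrier."""
    return be.BellEvansParams(k0=1.0 / 1470.0, gamma=0.5)


@pytest.fixture(scope="session")
def mutant_params() -> be.BellEvansParams:
    """Q39H kinetics: 8.1 s zero-force lifetime, 0.5 nm barrier."""
    return be.BellEvansParams(k0=1.0 / 8.1, gamma=0.5)
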