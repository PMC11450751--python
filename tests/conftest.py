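"""Shared fixtures: synthetic complexes exercised across the suite."""

import numpy as np
import pytest

from epitope_decomp import (
    PlantedContact,
    ToyComplexSpec,
    make_toy_complex,
)
from epitope_decomp.structures import Structure
from epitope_decomp.synthetic import build_ideal_chain


@pytest.fixture(scope="session")
def planted_complex():
    """Two-chain toy with one contact of each kind at a known distance."""
    spec = ToyComplexSpec(
        n_res_per_chain=8,
        planted_contacts=(
            PlantedContact("hbond", 2, 2, 2.90),
            PlantedContact("hydrophobic", 4, 4, 3.50),
            PlantedContact("salt_bridge", 6, 6, 3.20),
        ),
        seed=11,
    )
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def antibody_like():
    """Synthetic stand-in for a prepared Fv::epitope complex: heavy chain H
    (1–130) and light chain L (1–109) carrying the CDR sequences of
    aducanumab at author numbers 50–60 / 101–109 / 90–96, plus a short
    epitope chain A numbered 2–7."""
    one_to_three = {
        "V": "VAL", "I": "ILE", "W": "TRP", "F": "PHE", "D": "ASP", "G": "GLY",
        "T": "THR", "K": "LYS", "Y": "TYR", "Q": "GLN", "S": "SER", "P": "PRO",
        "L": "LEU", "A": "ALA", "R": "ARG", "E": "GLU", "H": "HIS", "N": "ASN",
    }
    h_names = ["GLY"] * 130
    for offset, letter in enumerate("VIWFDGTKKYY"):  # HCDR2, 50-60
        h_names[49 + offset] = one_to_three[letter]
    for offset, letter in enumerate("GIGARRGPY"):  # HCDR3, 101-109
        h_names[100 + offset] = one_to_three[letter]
    l_names = ["GLY"] * 109
    for offset, letter in enumerate("QSYSTPL"):  # LCDR3, 90-96
        l_names[89 + offset] = one_to_three[letter]
    a_names = [one_to_three[c] for c in "AEFRHD"]  # epitope residues 2-7

    chains = (
        build_ideal_chain("H", h_names, origin=(0.0, 0.0, 0.0))
        + build_ideal_chain("L", l_names, origin=(0.0, 12.0, 0.0))
        + build_ideal_chain("A", a_names, origin=(0.0, 24.0, 0.0), start_number=2)
    )
    return Structure(chains)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
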