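"""Shared study conditions for the analysis scripts.

One deterministic toy complex stands in for the prepared antibody::epitope
structure, and one planted 3-mode conformer ensemble stands in for the MD
trajectories.  All scripts rebuild these from the same seeds, so every step
is reproducible in isolation.
"""

from pathlib import Path

from epitope_decomp import EnsembleSpec, PlantedContact, ToyComplexSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"

SEED = 7

# two 8-residue chains, one planted contact of each class
TOY_SPEC = ToyComplexSpec(
    n_res_per_chain=8,
    planted_contacts=(
        PlantedContact("hbond", 2, 2, 2.90),
        PlantedContact("hydrophobic", 4, 4, 3.50),
        PlantedContact("salt_bridge", 6, 6, 3.20),
    ),
    seed=SEED,
)

# three displacement modes, 15 frames each, 0.1 Å coordinate noise
ENSEMBLE_SPEC = EnsembleSpec(
    k_modes=3, noise_sigma=0.1, n_frames_per_mode=15, seed=SEED
)

# the eight CDR-derived mimetic peptides (linear segments extracted from the
# antibody CDR hot spots H2 / H3 / L3, the S91Y point mutant of L3, and
# their disulfide-cyclized variants)
MIMETIC_PEPTIDES = {
    "Pep-H2-L": "VIWFDGTKKYY",
    "Pep-H2-C": "CVIWFDGTKKYYC",
    "Pep-H3-L": "GIGARRGPY",
    "Pep-H3-C": "CGIGARRGPYC",
    "Pep-L3-L1": "QSYSTPL",
    "Pep-L3-C1": "CQSYSTPLC",
    "Pep-L3-L2": "QYYSTPL",
    "Pep-L3-C2": "CQYYSTPLC",
}
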