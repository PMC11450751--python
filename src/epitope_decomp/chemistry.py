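"""Fixed chemistry tables shared by the contact detectors, the classical
energy backend, and the synthetic-structure builders.

All tables are keyed by PDB residue and atom names.  They are deliberately
small: backbone atoms plus the side-chain atoms that matter for hydrogen
bonds, hydrophobic contacts, salt bridges and a coarse electrostatic model.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Hydrogen-bond chemistry: donor heavy atoms (N/O/S bearing at least one H in
# the protonated structure) and acceptor atoms (N/O).  Backbone N donates,
# backbone O accepts, for every residue type.  His is both donor and acceptor.
# ---------------------------------------------------------------------------

BACKBONE_DONOR = "N"
BACKBONE_ACCEPTOR = "O"

SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

WATER_DONORS = ("O",)  # water oxygen both donates (via its H) and accepts
WATER_ACCEPTORS = ("O",)


def donor_atoms(res_name: str) -> tuple[str, ...]:
    side = SIDECHAIN_DONORS.get(res_name, ())
    return (BACKBONE_DONOR, *side)


def acceptor_atoms(res_name: str) -> tuple[str, ...]:
    side = SIDECHAIN_ACCEPTORS.get(res_name, ())
    return (BACKBONE_ACCEPTOR, "OXT", *side)


# ---------------------------------------------------------------------------
# Apolar carbons: side-chain carbons not covalently bonded to N or O.
# Used by the hydrophobic-contact detector (2.90–3.90 Å criterion).
# ---------------------------------------------------------------------------

APOLAR_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"),
    "PRO": ("CB", "CG"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "CYS": ("CB",),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "THR": ("CG2",),
    "GLU": ("CB", "CG"),
    "ASP": ("CB",),
    "GLN": ("CB", "CG"),
    "ASN": ("CB",),
    "HIS": ("CB",),
    "GLY": (),
    "SER": (),
}


# ---------------------------------------------------------------------------
# Salt-bridge groups at neutral pH: carboxylate oxygens vs. basic nitrogens.
# ---------------------------------------------------------------------------

ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}


# ---------------------------------------------------------------------------
# Classical backend parameters: coarse partial charges (e) and 12-6
# Lennard-Jones parameters per element.  The charge model is a desk-scale
# electrostatic stand-in: full formal charges on titratable side chains at
# pH 7, small backbone dipole charges elsewhere.  It preserves every
# structural aspect of the MFCC scheme without pretending to be a force field.
# ---------------------------------------------------------------------------

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

BACKBONE_CHARGES: dict[str, float] = {"N": -0.30, "H": 0.25, "CA": 0.05, "C": 0.45, "O": -0.45}

SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "ASP": {"CB": 0.0, "CG": 0.40, "OD1": -0.70, "OD2": -0.70},
    "GLU": {"CB": 0.0, "CG": 0.0, "CD": 0.40, "OE1": -0.70, "OE2": -0.70},
    "LYS": {"CB": 0.0, "CG": 0.0, "CD": 0.0, "CE": 0.20, "NZ": 0.80},
    "ARG": {"CB": 0.0, "CG": 0.0, "CD": 0.10, "NE": 0.10, "CZ": 0.30, "NH1": 0.25, "NH2": 0.25},
    "SER": {"CB": 0.05, "OG": -0.35, "HG": 0.30},
    "THR": {"CB": 0.05, "OG1": -0.35, "HG1": 0.30, "CG2": 0.0},
    "TYR": {"CZ": 0.10, "OH": -0.40, "HH": 0.30},
    "HIS": {"CB": 0.0, "CG": 0.10, "ND1": -0.30, "CD2": 0.10, "CE1": 0.20, "NE2": -0.10},
    "ASN": {"CB": 0.0, "CG": 0.40, "OD1": -0.55, "ND2": 0.15},
    "GLN": {"CB": 0.0, "CG": 0.0, "CD": 0.40, "OE1": -0.55, "NE2": 0.15},
}

# sigma (Å), epsilon (kcal/mol); hydrogens are LJ-inert
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
    "H": (0.00, 0.000),
    "X": (3.30, 0.100),
}


def default_charge(res_name: str, atom_name: str) -> float:
    if atom_name in BACKBONE_CHARGES:
        return BACKBONE_CHARGES[atom_name]
    return SIDECHAIN_CHARGES.get(res_name, {}).get(atom_name, 0.0)


# ---------------------------------------------------------------------------
# Amino-acid code tables
# ---------------------------------------------------------------------------

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = set(ONE_TO_THREE)
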