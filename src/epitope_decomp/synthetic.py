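"""Synthetic fixtures with known ground truth.

Every downstream stage is testable without external downloads: two-chain toy
complexes carry planted hydrogen-bond / hydrophobic / salt-bridge geometries
and an exactly pairwise-additive energy truth table; conformer ensembles are
drawn from k distinct displacement modes around a reference structure so
that clustering recovery can be scored against planted labels.

Chains use ideal extended backbone geometry (fixed bond lengths and angles,
φ = ψ = ω = 180°) built by natural-extension internal coordinates.  Contacts
are planted by placing the relevant side-chain atoms directly on the
inter-chain axis at the requested distance, so each planted distance is
exact.  All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, ResidueLookupError, SequenceError
from .chemistry import ONE_TO_THREE
from .mfcc import ClassicalBackend
from .structures import Atom, Residue, ResidueRef, Structure, Trajectory

# ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_C_N_CA, A_N_CA_C, A_CA_C_N, A_CA_C_O = 121.9, 111.0, 116.6, 120.5


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension (NeRF) placement: position d with |cd| = bond,
    angle(b,c,d) = angle and torsion(a,b,c,d) = torsion."""
    angle, torsion = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise GenerationError("collinear reference atoms in NeRF placement")
    n = n / norm
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_ideal_chain(
    chain_id: str,
    res_names: Sequence[str],
    origin: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    start_number: int = 1,
) -> list[Residue]:
    """Extended poly-peptide backbone (N, CA, C, O per residue)."""
    origin = np.asarray(origin, dtype=float)
    residues: list[Residue] = []
    prev: dict[str, np.ndarray] | None = None
    for i, res_name in enumerate(res_names):
        if prev is None:
            n = origin
            ca = n + np.array([B_N_CA, 0.0, 0.0])
            # pseudo-atom fixes the in-plane orientation of the first carbonyl
            c = place_atom(n + np.array([-1.0, 0.3, 0.0]), n, ca, B_CA_C, A_N_CA_C, 180.0)
        else:
            n = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, 180.0)  # psi
            ca = place_atom(prev["CA"], prev["C"], n, B_N_CA, A_C_N_CA, 180.0)        # omega
            c = place_atom(prev["C"], n, ca, B_CA_C, A_N_CA_C, 180.0)                  # phi
        ref = ResidueRef(chain_id, start_number + i, "", res_name)
        res = Residue(ref, [
            Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
        ])
        # carbonyl oxygen anti to the next amide nitrogen (psi + 180)
        res.atoms.append(Atom("O", "O", place_atom(n, ca, c, B_C_O, A_CA_C_O, 0.0)))
        residues.append(res)
        prev = {"N": n, "CA": ca, "C": c}
    return residues


# ---------------------------------------------------------------------------
# Toy complexes with planted contacts
# ---------------------------------------------------------------------------

# residue types and atoms used to realize each planted contact kind:
# (resname_a, atom_a, resname_b, atom_b); for hbond the chain-B side donates
_CONTACT_ATOMS = {
    "hbond": ("ASP", "OD1", "SER", "OG"),
    "hydrophobic": ("ALA", "CB", "ALA", "CB"),
    "salt_bridge": ("GLU", "OE1", "LYS", "NZ"),
}

@dataclass(frozen=True)
class PlantedContact:
    kind: str  # hbond | hydrophobic | salt_bridge
    res_a: int  # 1-based residue number on chain A
    res_b: int  # 1-based residue number on chain B
    distance: float  # Å between the two planted atoms

    def __post_init__(self) -> None:
        if self.kind not in _CONTACT_ATOMS:
            raise GenerationError(f"unknown planted contact kind {self.kind!r}")
        if self.distance <= 0:
            raise GenerationError("planted distance must be positive")


@dataclass
class ToyComplexSpec:
    n_res_per_chain: int = 6
    planted_contacts: tuple[PlantedContact, ...] = ()
    charge_assignment: Mapping[tuple[str, int, str], float] | None = None
    seed: int = 0
    chain_a: str = "A"
    chain_b: str = "B"
    gap: float = 10.0  # Å between the two backbones
    dielectric: float = 40.0


@dataclass
class ToyGroundTruth:
    """Sufficient statistics of a generated toy complex."""

    contacts: list[tuple[str, ResidueRef, str, ResidueRef, str, float]]
    pair_energies: dict[tuple[ResidueRef, ResidueRef], float]
    backend: ClassicalBackend


def _truth_charge_fn(assignment: Mapping[tuple[str, int, str], float]):
    def charge(ref: ResidueRef, atom_name: str) -> float:
        return assignment.get((ref.chain_id, ref.seq_number, atom_name), 0.0)

    return charge


def random_charges(
    structure: Structure, rng: np.random.Generator, scale: float = 0.5
) -> dict[tuple[str, int, str], float]:
    """Uniform random partial charges for every real atom (used to exercise
    the MFCC identity under arbitrary pairwise-additive electrostatics)."""
    return {
        (res.ref.chain_id, res.ref.seq_number, atom.name):
            float(rng.uniform(-scale, scale))
        for res, atom in structure.iter_atoms()
        if not atom.is_fill
    }


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, ToyGroundTruth]:
    """Two extended chains with each planted contact realized exactly.

    Chain A runs along x at y = 0, chain B parallel at y = ``gap``.  A planted
    contact positions one side-chain atom on each chain on the vertical line
    through the chain-A residue's Cα, separated by exactly the target
    distance.  Residues not involved in any contact are glycine.
    """
    n = spec.n_res_per_chain
    used: set[tuple[str, int]] = set()
    for pc in spec.planted_contacts:
        for chain, num in ((spec.chain_a, pc.res_a), (spec.chain_b, pc.res_b)):
            if not 1 <= num <= n:
                raise GenerationError(f"contact residue {chain}:{num} outside 1..{n}")
            if (chain, num) in used:
                raise GenerationError(
                    f"residue {chain}:{num} participates in more than one planted contact"
                )
            used.add((chain, num))
        if pc.distance >= spec.gap - 4.0:
            raise GenerationError(
                f"planted distance {pc.distance} infeasible for gap {spec.gap}: "
                "the planted atoms would collide with a backbone"
            )

    names_a = ["GLY"] * n
    names_b = ["GLY"] * n
    for pc in spec.planted_contacts:
        ra, _, rb, _ = _CONTACT_ATOMS[pc.kind]
        names_a[pc.res_a - 1] = ra
        names_b[pc.res_b - 1] = rb

    chain_a = build_ideal_chain(spec.chain_a, names_a, origin=(0.0, 0.0, 0.0))
    chain_b = build_ideal_chain(spec.chain_b, names_b, origin=(0.0, spec.gap, 0.0))
    structure = Structure(chain_a + chain_b)

    truth_contacts = []
    for pc in spec.planted_contacts:
        _, atom_a, res_name_b, atom_b = _CONTACT_ATOMS[pc.kind]
        res_a = chain_a[pc.res_a - 1]
        res_b = chain_b[pc.res_b - 1]
        # planted atoms sit on the Cα–Cα axis, centred midway between the
        # two backbones so neither comes near the partner chain
        ca_a = res_a.atom("CA").coords
        ca_b = res_b.atom("CA").coords
        axis = ca_b - ca_a
        span = float(np.linalg.norm(axis))
        if span < pc.distance + 4.0:
            raise GenerationError(
                f"planted distance {pc.distance} infeasible: backbones only "
                f"{span:.1f} Å apart"
            )
        u = axis / span
        mid = 0.5 * (ca_a + ca_b)
        pos_a = mid - 0.5 * pc.distance * u
        pos_b = mid + 0.5 * pc.distance * u
        elem_a = "O" if atom_a.startswith("O") else "C"
        elem_b = "O" if atom_b.startswith("O") else ("N" if atom_b.startswith("N") else "C")
        res_a.atoms.append(Atom(atom_a, elem_a, pos_a))
        res_b.atoms.append(Atom(atom_b, elem_b, pos_b))
        if pc.kind == "hbond":  # protonate the donor, H pointing at the acceptor
            res_b.atoms.append(Atom("HG", "H", pos_b - 1.0 * u, is_hydrogen=True))
        truth_contacts.append(
            (pc.kind, res_a.ref, atom_a, res_b.ref, atom_b, pc.distance)
        )

    assignment = spec.charge_assignment
    backend = ClassicalBackend(
        dielectric=spec.dielectric,
        charge_fn=_truth_charge_fn(assignment) if assignment is not None else None,
    )
    pair_energies = {
        (ra.ref, rb.ref): backend.pair_interaction(structure, ra.ref, rb.ref)
        for ra in chain_a
        for rb in chain_b
    }
    return structure, ToyGroundTruth(truth_contacts, pair_energies, backend)


# ---------------------------------------------------------------------------
# Conformer ensembles with planted modes
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    k_modes: int = 3
    mode_vectors: tuple[tuple[float, float, float], ...] | None = None
    noise_sigma: float = 0.1  # Å, iid Gaussian on every coordinate
    n_frames_per_mode: int = 20
    seed: int = 0
    displaced_fraction: float = 0.5  # trailing fraction of first-chain residues displaced

    def resolved_modes(self) -> np.ndarray:
        if self.mode_vectors is not None:
            modes = np.asarray(self.mode_vectors, dtype=float)
        else:
            # slide the displaced block along the chain axis: inter-residue
            # distances then separate the modes to first order
            step = max(1.0, 6.0 * self.noise_sigma)
            modes = np.array([[m * step, 0.0, 0.0] for m in range(self.k_modes)])
        if len(modes) != self.k_modes:
            raise GenerationError("mode_vectors length must equal k_modes")
        for i in range(len(modes)):
            for j in range(i + 1, len(modes)):
                sep = np.linalg.norm(modes[i] - modes[j])
                if self.noise_sigma > 0 and sep <= 5.0 * self.noise_sigma:
                    raise GenerationError(
                        f"modes {i},{j} separated by {sep:.2f} Å "
                        f"<= 5 sigma ({5 * self.noise_sigma:.2f} Å): not recoverable"
                    )
        return modes


def make_conformers(
    base: Structure, spec: EnsembleSpec
) -> tuple[Trajectory, np.ndarray]:
    """Frames = base + per-mode displacement of a residue subset + iid noise.

    The displacement moves the trailing ``displaced_fraction`` of the first
    chain's residues, so the modes differ in internal geometry (inter-residue
    distances), not merely by a rigid motion.  Returns the trajectory and the
    true mode label of every frame.
    """
    rng = np.random.default_rng(spec.seed)
    modes = spec.resolved_modes()
    chain_id = base.chain_ids()[0]
    chain = base.chain(chain_id)
    n_moved = max(1, int(len(chain) * spec.displaced_fraction))
    moved_keys = {r.ref.key for r in chain[len(chain) - n_moved:]}

    frames: list[Structure] = []
    labels: list[int] = []
    for mode_idx in range(spec.k_modes):
        for _ in range(spec.n_frames_per_mode):
            frame = base.copy()
            for res in frame.residues:
                displace = res.ref.key in moved_keys
                for atom in res.atoms:
                    if displace:
                        atom.coords = atom.coords + modes[mode_idx]
                    if spec.noise_sigma > 0:
                        atom.coords = atom.coords + rng.normal(
                            0.0, spec.noise_sigma, size=3
                        )
            frames.append(frame)
            labels.append(mode_idx)
    return Trajectory(frames), np.asarray(labels)


# ---------------------------------------------------------------------------
# Idealized point mutation
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}

# stick templates: side-chain atoms at increasing distance from CA along the
# idealized Cβ direction.  Deliberately approximate — enough for sequence-level
# work and coarse geometry, not for packing.
SIDECHAIN_STICKS: dict[str, tuple[tuple[str, float], ...]] = {
    "GLY": (),
    "ALA": (("CB", 1.53),),
    "SER": (("CB", 1.53), ("OG", 2.9)),
    "CYS": (("CB", 1.53), ("SG", 3.3)),
    "THR": (("CB", 1.53), ("OG1", 2.9), ("CG2", 2.9)),
    "VAL": (("CB", 1.53), ("CG1", 2.9), ("CG2", 2.9)),
    "LEU": (("CB", 1.53), ("CG", 2.9), ("CD1", 4.2), ("CD2", 4.2)),
    "ILE": (("CB", 1.53), ("CG1", 2.9), ("CG2", 2.9), ("CD1", 4.2)),
    "MET": (("CB", 1.53), ("CG", 2.9), ("SD", 4.5), ("CE", 5.9)),
    "PRO": (("CB", 1.53), ("CG", 2.9)),
    "PHE": (("CB", 1.53), ("CG", 3.0), ("CD1", 4.0), ("CD2", 4.0), ("CE1", 5.2),
             ("CE2", 5.2), ("CZ", 5.8)),
    "TYR": (("CB", 1.53), ("CG", 3.0), ("CD1", 4.0), ("CD2", 4.0), ("CE1", 5.2),
             ("CE2", 5.2), ("CZ", 5.8), ("OH", 7.2)),
    "TRP": (("CB", 1.53), ("CG", 3.0), ("CD2", 4.2), ("NE1", 4.4), ("CE3", 5.0),
             ("CZ2", 6.0), ("CZ3", 6.2), ("CH2", 6.8)),
    "ASP": (("CB", 1.53), ("CG", 2.9), ("OD1", 4.0), ("OD2", 4.0)),
    "GLU": (("CB", 1.53), ("CG", 2.9), ("CD", 4.2), ("OE1", 5.3), ("OE2", 5.3)),
    "ASN": (("CB", 1.53), ("CG", 2.9), ("OD1", 4.0), ("ND2", 4.0)),
    "GLN": (("CB", 1.53), ("CG", 2.9), ("CD", 4.2), ("OE1", 5.3), ("NE2", 5.3)),
    "HIS": (("CB", 1.53), ("CG", 3.0), ("ND1", 4.1), ("CD2", 4.2), ("CE1", 5.2),
             ("NE2", 5.3)),
    "LYS": (("CB", 1.53), ("CG", 2.9), ("CD", 4.2), ("CE", 5.5), ("NZ", 6.7)),
    "ARG": (("CB", 1.53), ("CG", 2.9), ("CD", 4.2), ("NE", 5.5), ("CZ", 6.3),
             ("NH1", 7.2), ("NH2", 7.2)),
}


def make_mutant(base: Structure, site: ResidueRef, to: str) -> Structure:
    """Rename a residue and replace its side chain with an idealized stick
    template aligned on the backbone (approximate geometry, exact sequence).

    Backbone atoms are never moved; mutating to the current residue type
    returns an unchanged copy.
    """
    to = to.upper()
    if len(to) == 1:
        try:
            to = ONE_TO_THREE[to]
        except KeyError:
            raise SequenceError(f"unknown amino acid {to!r}") from None
    if to not in SIDECHAIN_STICKS:
        raise SequenceError(f"unknown residue name {to!r}")

    mutant = base.copy()
    if site not in mutant:
        raise ResidueLookupError(f"mutation site {site} not in structure")
    res = mutant.residue(site)
    if res.ref.res_name == to:
        return mutant

    n, ca, c = (res.atom(a).coords for a in ("N", "CA", "C"))
    cb_dir = place_atom(n, c, ca, 1.0, 110.5, -122.0) - ca
    cb_dir = cb_dir / np.linalg.norm(cb_dir)

    res.atoms = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    for atom_name, length in SIDECHAIN_STICKS[to]:
        element = atom_name[0] if atom_name[0] in "CNOS" else "C"
        res.atoms.append(Atom(atom_name, element, ca + length * cb_dir))

    new_ref = ResidueRef(site.chain_id, site.seq_number, site.insertion_code, to)
    res.ref = new_ref
    # refresh the lookup index with the renamed residue
    return Structure([r for r in mutant.residues], mutant.model_id)
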