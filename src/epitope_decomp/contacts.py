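"""Geometric detection of interface contacts.

Hydrogen bonds follow the LigPlot+/HBPLUS distance convention: a bond is
recorded when the hydrogen–acceptor distance is at most ``hbond_ha_max``
(2.70 Å) *and* the donor–acceptor distance is at most ``hbond_da_max``
(3.35 Å).  No angular criterion is applied.  Hydrophobic contacts require an
apolar-carbon pair within [2.90, 3.90] Å.  Salt bridges (carboxylate oxygen
to basic nitrogen) use a conventional 4.0 Å cutoff, configurable since the
criterion is not standardized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .errors import ConfigError, ModeError
from .structures import Atom, Residue, ResidueRef, Structure

H_BOND_COVALENT_MAX = 1.3  # Å: a hydrogen is "attached" to the nearest heavy atom below this
_EPS = 1e-9  # float guard so that a distance exactly at a criterion qualifies


@dataclass(frozen=True)
class ContactCriteria:
    """Distance thresholds (Å) for the three contact classes."""

    hbond_ha_max: float = 2.70
    hbond_da_max: float = 3.35
    hydrophobic_min: float = 2.90
    hydrophobic_max: float = 3.90
    salt_bridge_max: float = 4.00

    def __post_init__(self) -> None:
        vals = (self.hbond_ha_max, self.hbond_da_max, self.hydrophobic_min,
                self.hydrophobic_max, self.salt_bridge_max)
        if any(v <= 0 for v in vals):
            raise ConfigError("all contact criteria must be positive")
        if self.hydrophobic_min >= self.hydrophobic_max:
            raise ConfigError("hydrophobic_min must be < hydrophobic_max")


@dataclass(frozen=True)
class ContactRecord:
    """One detected contact.  For hydrogen bonds res1/atom1 is the donor side
    and res2/atom2 the acceptor; d_pair is then the donor–acceptor distance."""

    kind: str  # hbond | hydrophobic | salt_bridge
    res1: ResidueRef
    atom1: str
    res2: ResidueRef
    atom2: str
    d_pair: float
    d_ha: float | None = None

    @property
    def residue_key(self) -> tuple[str, ...]:
        """Order-free residue-pair key used for conservation counting."""
        a = (self.res1.chain_id, str(self.res1.seq_number) + self.res1.insertion_code,
             self.res1.res_name)
        b = (self.res2.chain_id, str(self.res2.seq_number) + self.res2.insertion_code,
             self.res2.res_name)
        lo, hi = sorted((a, b))
        return (self.kind, *lo, *hi)

    def __str__(self) -> str:
        return f"{self.kind}: {self.res1}({self.atom1})::{self.res2}({self.atom2}) d={self.d_pair:.2f}"


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


def _split_groups(
    structure: Structure, chain_pair: tuple[Iterable[str], Iterable[str]]
) -> tuple[list[Residue], list[Residue]]:
    g1, g2 = set(chain_pair[0]), set(chain_pair[1])
    if g1 & g2:
        raise ConfigError(f"chain groups overlap: {sorted(g1 & g2)}")
    side1 = [r for r in structure.polymer_residues() if r.ref.chain_id in g1]
    side2 = [r for r in structure.polymer_residues() if r.ref.chain_id in g2]
    return side1, side2


def _candidate_pairs(
    side1: Sequence[Residue], side2: Sequence[Residue], cutoff: float
) -> Iterable[tuple[Residue, Residue]]:
    """Residue pairs whose bounding spheres may come within ``cutoff``."""
    c1 = [r.coord_array().mean(axis=0) for r in side1]
    r1 = [np.linalg.norm(r.coord_array() - c, axis=1).max() for r, c in zip(side1, c1)]
    c2 = [r.coord_array().mean(axis=0) for r in side2]
    r2 = [np.linalg.norm(r.coord_array() - c, axis=1).max() for r, c in zip(side2, c2)]
    for i, ri in enumerate(side1):
        for j, rj in enumerate(side2):
            if np.linalg.norm(c1[i] - c2[j]) <= cutoff + r1[i] + r2[j]:
                yield ri, rj


def _attached_hydrogens(res: Residue, heavy: Atom) -> list[Atom]:
    return [
        h for h in res.atoms
        if h.is_hydrogen and _dist(h, heavy) <= H_BOND_COVALENT_MAX
    ]


def detect_hbonds(
    structure: Structure,
    chain_pair: tuple[Iterable[str], Iterable[str]],
    criteria: ContactCriteria = ContactCriteria(),
    mode: str = "with_hydrogens",
) -> list[ContactRecord]:
    """Hydrogen bonds across the interface.

    ``with_hydrogens``: both the H···A (<= hbond_ha_max) and D···A
    (<= hbond_da_max) criteria must hold for a donor/acceptor pair from the
    chemistry tables.  ``heavy_only``: the D···A criterion alone (for
    structures without protons).  One record per qualifying atom pair.
    """
    if mode not in ("with_hydrogens", "heavy_only"):
        raise ConfigError(f"unknown h-bond mode {mode!r}")
    side1, side2 = _split_groups(structure, chain_pair)
    if mode == "with_hydrogens" and not structure.has_hydrogens():
        raise ModeError("with_hydrogens mode requires polar hydrogens in the structure")

    records: list[ContactRecord] = []
    reach = criteria.hbond_da_max
    for ri, rj in _candidate_pairs(side1, side2, reach):
        for donor_res, acceptor_res in ((ri, rj), (rj, ri)):
            for dname in chemistry.donor_atoms(donor_res.ref.res_name):
                if not donor_res.has_atom(dname):
                    continue
                donor = donor_res.atom(dname)
                hydrogens = (
                    _attached_hydrogens(donor_res, donor)
                    if mode == "with_hydrogens"
                    else []
                )
                if mode == "with_hydrogens" and not hydrogens:
                    continue  # unprotonated nitrogen/oxygen cannot donate
                for aname in chemistry.acceptor_atoms(acceptor_res.ref.res_name):
                    if not acceptor_res.has_atom(aname):
                        continue
                    acceptor = acceptor_res.atom(aname)
                    d_da = _dist(donor, acceptor)
                    if d_da > criteria.hbond_da_max + _EPS:
                        continue
                    if mode == "heavy_only":
                        records.append(ContactRecord(
                            "hbond", donor_res.ref, dname,
                            acceptor_res.ref, aname, d_da))
                        continue
                    d_ha = min(_dist(h, acceptor) for h in hydrogens)
                    if d_ha <= criteria.hbond_ha_max + _EPS:
                        records.append(ContactRecord(
                            "hbond", donor_res.ref, dname,
                            acceptor_res.ref, aname, d_da, d_ha=d_ha))
    return records


def detect_hydrophobic(
    structure: Structure,
    chain_pair: tuple[Iterable[str], Iterable[str]],
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Apolar-carbon pairs with distance in [hydrophobic_min, hydrophobic_max]."""
    side1, side2 = _split_groups(structure, chain_pair)
    records: list[ContactRecord] = []
    for ri, rj in _candidate_pairs(side1, side2, criteria.hydrophobic_max):
        for a1 in chemistry.APOLAR_CARBONS.get(ri.ref.res_name, ()):
            if not ri.has_atom(a1):
                continue
            for a2 in chemistry.APOLAR_CARBONS.get(rj.ref.res_name, ()):
                if not rj.has_atom(a2):
                    continue
                d = _dist(ri.atom(a1), rj.atom(a2))
                if criteria.hydrophobic_min - _EPS <= d <= criteria.hydrophobic_max + _EPS:
                    records.append(ContactRecord(
                        "hydrophobic", ri.ref, a1, rj.ref, a2, d))
    return records


def detect_salt_bridges(
    structure: Structure,
    chain_pair: tuple[Iterable[str], Iterable[str]],
    criteria: ContactCriteria = ContactCriteria(),
) -> list[ContactRecord]:
    """Asp/Glu carboxylate oxygen within ``salt_bridge_max`` of a basic nitrogen."""
    side1, side2 = _split_groups(structure, chain_pair)
    records: list[ContactRecord] = []
    for ri, rj in _candidate_pairs(side1, side2, criteria.salt_bridge_max):
        for acid_res, base_res in ((ri, rj), (rj, ri)):
            for oname in chemistry.ACIDIC_ATOMS.get(acid_res.ref.res_name, ()):
                if not acid_res.has_atom(oname):
                    continue
                for nname in chemistry.BASIC_ATOMS.get(base_res.ref.res_name, ()):
                    if not base_res.has_atom(nname):
                        continue
                    d = _dist(acid_res.atom(oname), base_res.atom(nname))
                    if d <= criteria.salt_bridge_max + _EPS:
                        records.append(ContactRecord(
                            "salt_bridge", acid_res.ref, oname,
                            base_res.ref, nname, d))
    return records


def collapse_residues(records: Iterable[ContactRecord]) -> list[ContactRecord]:
    """Keep one record (the shortest) per residue pair and kind."""
    best: dict[tuple, ContactRecord] = {}
    for rec in records:
        key = rec.residue_key
        if key not in best or rec.d_pair < best[key].d_pair:
            best[key] = rec
    return list(best.values())


@dataclass
class ConservationSummary:
    """How often each contact (residue pair + kind) recurs across conformations."""

    counts: dict[tuple, int] = field(default_factory=dict)
    n_conformations: int = 0

    def conserved(self, min_count: int) -> list[tuple]:
        return [k for k, c in sorted(self.counts.items()) if c >= min_count]


def conservation(contact_lists: Sequence[Sequence[ContactRecord]]) -> ConservationSummary:
    """Count, per contact key, the conformations in which it appears."""
    if not contact_lists:
        raise ConfigError("conservation requires at least one conformation")
    counter: Counter = Counter()
    for records in contact_lists:
        counter.update({rec.residue_key for rec in records})
    return ConservationSummary(dict(counter), len(contact_lists))


def contacts_to_frame(records: Iterable[ContactRecord]) -> pd.DataFrame:
    rows = [
        {
            "kind": r.kind,
            "chain1": r.res1.chain_id, "res1": r.res1.seq_number,
            "resname1": r.res1.res_name, "atom1": r.atom1,
            "chain2": r.res2.chain_id, "res2": r.res2.seq_number,
            "resname2": r.res2.res_name, "atom2": r.atom2,
            "d_ha": r.d_ha, "d_pair": r.d_pair,
        }
        for r in records
    ]
    cols = ["kind", "chain1", "res1", "resname1", "atom1",
            "chain2", "res2", "resname2", "atom2", "d_ha", "d_pair"]
    return pd.DataFrame(rows, columns=cols)
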