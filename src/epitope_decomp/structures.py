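"""Coordinate model and PDB I/O.

The hierarchy is deliberately flat: a :class:`Structure` is an ordered list of
residues (each a :class:`ResidueRef` plus its atoms), grouped by chain on
demand.  Author (file) residue numbering is the single coordinate system used
everywhere downstream — interface residues are referred to by their
crystallographic numbers (e.g. heavy-chain VAL50, light-chain SER91), so no
renumbering ever happens.

Parsing is delegated to Bio.PDB; writing uses the fixed-column PDB format
directly so that round-trips preserve residue identity and coordinates to
three decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    PDBParseError,
    ResidueLookupError,
)

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"}


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of one residue: chain, author sequence number, insertion code, name."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    res_name: str = ""

    def __str__(self) -> str:  # e.g. "L:SER91"
        return f"{self.chain_id}:{self.res_name}{self.seq_number}{self.insertion_code}"

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity without the residue name (used for lookups)."""
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    is_hydrogen: bool = False
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_fill: bool = False  # true only for MFCC fill hydrogens

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol must be non-empty")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def is_water(self) -> bool:
        return self.ref.res_name in WATER_NAMES

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise ResidueLookupError(f"{self.ref} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coord_array(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)

    def copy(self) -> "Residue":
        return Residue(self.ref, [a.copy() for a in self.atoms], self.het)


class Structure:
    """One conformation: an ordered list of residues with stable chain order."""

    def __init__(self, residues: Iterable[Residue] = (), model_id: int = 0):
        self.residues: list[Residue] = list(residues)
        self.model_id = model_id
        self._index: dict[tuple[str, int, str], Residue] = {
            r.ref.key: r for r in self.residues
        }

    # -- construction -------------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        self.residues.append(residue)
        self._index[residue.ref.key] = residue

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.model_id)

    # -- queries ------------------------------------------------------------
    def __len__(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def __contains__(self, ref: ResidueRef) -> bool:
        return ref.key in self._index

    def residue(self, ref: ResidueRef) -> Residue:
        try:
            return self._index[ref.key]
        except KeyError:
            raise ResidueLookupError(f"residue {ref} not in structure") from None

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.ref.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str, polymer_only: bool = True) -> list[Residue]:
        return [
            r
            for r in self.residues
            if r.ref.chain_id == chain_id and not (polymer_only and r.is_water)
        ]

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water]

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def coord_array(self) -> np.ndarray:
        return np.array(
            [a.coords for _, a in self.iter_atoms()], dtype=float
        ).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        for (_, atom), xyz in zip(self.iter_atoms(), coords):
            atom.coords = xyz.copy()

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for _, a in self.iter_atoms())


@dataclass
class Trajectory:
    """Ordered conformations sharing one topology (a multi-model PDB stands in
    for an MD trajectory)."""

    frames: list[Structure]
    frame_times: list[float] | None = None  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyStructureError("trajectory has no frames")
        n0 = len(self.frames[0])
        names0 = [(r.ref.key, a.name) for r, a in self.frames[0].iter_atoms()]
        for i, f in enumerate(self.frames[1:], start=1):
            if len(f) != n0 or [(r.ref.key, a.name) for r, a in f.iter_atoms()] != names0:
                raise ValueError(f"frame {i} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coord_array() for f in self.frames])


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"{path}, line {lineno}: truncated ATOM record")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"{path}, line {lineno}: malformed coordinates in ATOM record"
                    ) from None


def read_pdb(path: str | Path, keep_waters: bool = True) -> list[Structure]:
    """Read a (possibly multi-MODEL) PDB file into one Structure per model.

    Residue numbering, insertion codes and chain IDs are preserved verbatim.
    For altloc ensembles only the highest-occupancy conformer of each atom is
    kept.  HETATM waters are captured iff ``keep_waters``.
    """
    path = Path(path)
    _validate_pdb_lines(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # pragma: no cover - defensive
        raise PDBParseError(f"{path}: {exc}") from exc

    models: list[Structure] = []
    for model in bio:
        struct = Structure(model_id=model.id)
        for chain in model:
            for res in chain:
                hetfield, seq, icode = res.id
                name = res.get_resname().strip()
                is_water = hetfield == "W" or name in WATER_NAMES
                if is_water and not keep_waters:
                    continue
                ref = ResidueRef(chain.id, seq, icode.strip(), name)
                residue = Residue(ref, het=bool(hetfield.strip()))
                for atom in res:
                    if atom.is_disordered():
                        atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
                    elem = (atom.element or atom.get_name()[0]).strip().upper()
                    residue.atoms.append(
                        Atom(
                            name=atom.get_name(),
                            element=elem or "X",
                            coords=np.asarray(atom.get_coord(), dtype=float),
                            is_hydrogen=elem == "H",
                            occupancy=atom.get_occupancy() or 1.0,
                            bfactor=atom.get_bfactor() or 0.0,
                        )
                    )
                if residue.atoms:
                    struct.add_residue(residue)
        if len(struct) == 0:
            raise EmptyStructureError(f"{path}: model {model.id} contains no atoms")
        models.append(struct)
    if not models:
        raise EmptyStructureError(f"{path}: no atoms found")
    return models


def read_trajectory(path: str | Path, keep_waters: bool = False) -> Trajectory:
    """Read a multi-model PDB as a Trajectory."""
    return Trajectory(read_pdb(path, keep_waters=keep_waters))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(
    serial: int, atom: Atom, res: Residue, het: bool
) -> str:
    record = "HETATM" if het else "ATOM  "
    name = atom.name
    if len(name) < 4:
        # standard alignment: element-start at column 14 for short names
        name = f" {name:<3s}"
    x, y, z = atom.coords
    return (
        f"{record}{serial:5d} {name:<4.4s} {res.ref.res_name:>3.3s} "
        f"{res.ref.chain_id:1.1s}{res.ref.seq_number:4d}{(res.ref.insertion_code or ' '):1.1s}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
        f"          {atom.element:>2.2s}"
    )


def _write_model(fh, structure: Structure, serial_start: int = 1) -> int:
    serial = serial_start
    prev_chain: str | None = None
    last_polymer: Residue | None = None
    for res in structure.residues:
        if prev_chain is not None and res.ref.chain_id != prev_chain and last_polymer:
            fh.write("TER\n")
        for atom in res.atoms:
            het = res.het or res.is_water
            fh.write(_format_atom_line(serial, atom, res, het) + "\n")
            serial += 1
        prev_chain = res.ref.chain_id
        if not res.is_water:
            last_polymer = res
    fh.write("TER\n")
    return serial


def write_pdb(structure: Structure | Sequence[Structure] | Trajectory, path: str | Path) -> None:
    """Write a Structure (or several, as MODEL blocks) in PDB format.

    Coordinates are rendered with 3 decimals; output is re-readable by
    :func:`read_pdb` with identical residue identity.
    """
    if isinstance(structure, Trajectory):
        models: Sequence[Structure] = structure.frames
    elif isinstance(structure, Structure):
        models = [structure]
    else:
        models = list(structure)
    if not models or all(len(m) == 0 for m in models):
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    with open(path, "w") as fh:
        if len(models) == 1:
            _write_model(fh, models[0])
        else:
            for i, m in enumerate(models, start=1):
                fh.write(f"MODEL {i:8d}\n")
                _write_model(fh, m)
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selection and geometry
# ---------------------------------------------------------------------------

def select_residues(
    structure: Structure,
    chain_ids: Iterable[str],
    ranges: Sequence[tuple[int, int]] | Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> Structure:
    """Sub-structure of the residues in ``chain_ids`` whose author sequence
    numbers fall in the given inclusive intervals (all residues of the chain
    when ``ranges`` is None).  Intervals may be chain-specific via a mapping.
    """
    chain_ids = set(chain_ids)

    def _keep(ref: ResidueRef) -> bool:
        if ref.chain_id not in chain_ids:
            return False
        if ranges is None:
            return True
        intervals = (
            ranges.get(ref.chain_id, []) if isinstance(ranges, Mapping) else ranges
        )
        return any(lo <= ref.seq_number <= hi for lo, hi in intervals)

    picked = [r.copy() for r in structure.residues if _keep(r.ref)]
    if not picked:
        raise EmptySelectionError(
            f"selection {sorted(chain_ids)} / {ranges!r} matched no residues"
        )
    return Structure(picked, structure.model_id)


def min_residue_distance(
    a: ResidueRef,
    b: ResidueRef,
    structure: Structure,
    heavy_only: bool = True,
) -> float:
    """Minimum inter-atomic distance (Å) between two residues; symmetric."""
    ra = structure.residue(a).coord_array(heavy_only=heavy_only)
    rb = structure.residue(b).coord_array(heavy_only=heavy_only)
    if ra.size == 0 or rb.size == 0:
        raise EmptySelectionError(f"no qualifying atoms for {a} / {b}")
    diff = ra[:, None, :] - rb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())
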