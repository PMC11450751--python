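"""Mimetic-peptide design and sequence-based physicochemical panel.

Linear peptides are extracted verbatim from hot-spot regions (CDR segments)
of the antibody chains; cyclic variants add an N- and a C-terminal cysteine
joined by a disulfide.  The property panel follows the conventions of the
standard web calculators so that values are comparable with the literature:

* molecular weight — sum of average residue masses plus one water
  (ProtParam convention; cyclic peptides are reported on the linear chain,
  without the −2H disulfide correction);
* isoelectric point — bisection root of the Henderson–Hasselbalch net-charge
  function with the Bjellqvist pKa set, including residue-specific
  N-terminal pKas (ProtParam convention);
* net charge — integer (#K + #R) − (#D + #E) at neutral pH, His and termini
  excluded (antimicrobial-peptide-database convention);
* protease cleavage sites — PeptideCutter position-specific rule matrices
  for trypsin, chymotrypsin (high/low specificity) and pepsin (pH 1.3 and
  pH > 2), with terminal residues counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import pandas as pd

from .chemistry import STANDARD_AA, THREE_TO_ONE
from .errors import ConfigError, MissingResidueError, SequenceError
from .profiles import RegionDef
from .structures import Structure

WATER_MASS = 18.0153

# ExPASy average residue masses (Da)
RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Bjellqvist pKa set as used by ProtParam: side chains, C-terminus (default
# plus residue-specific), and residue-specific N-terminal pKas.
PKA_POSITIVE_SIDE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE_SIDE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERM_DEFAULT = 3.55
PKA_CTERM = {"D": 4.55, "E": 4.75}


def _check_sequence(sequence: str) -> str:
    sequence = sequence.strip().upper()
    if not sequence:
        raise SequenceError("empty peptide sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise SequenceError(f"non-standard letters in sequence: {sorted(bad)}")
    return sequence


# ---------------------------------------------------------------------------
# Peptide records and design operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideRecord:
    name: str
    sequence: str
    cyclic: bool = False
    source: RegionDef | None = None
    mutations: tuple[tuple[int, str, str], ...] = ()  # (seq_number, from, to)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence))
        if self.cyclic and not (
            self.sequence[0] == "C" and self.sequence[-1] == "C"
        ):
            raise SequenceError(
                "a cyclic peptide must carry terminal cysteines for the disulfide"
            )


def extract_segment(
    structure: Structure, region: RegionDef, name: str | None = None
) -> PeptideRecord:
    """One-letter sequence of a region's residues, in chain order.

    A gap (missing sequence number inside an interval) raises, since the
    linear mimetic must correspond precisely to the isolated segment.
    """
    chain = structure.chain(region.chain_id)
    letters: list[str] = []
    for lo, hi in region.ranges:
        for number in range(lo, hi + 1):
            match = [r for r in chain if r.ref.seq_number == number]
            if not match:
                raise MissingResidueError(
                    f"region {region.name}: residue {region.chain_id}:{number} missing"
                )
            res_name = match[0].ref.res_name
            if res_name not in THREE_TO_ONE:
                raise SequenceError(f"non-standard residue {res_name} in {region.name}")
            letters.append(THREE_TO_ONE[res_name])
    return PeptideRecord(
        name=name or region.name, sequence="".join(letters), source=region
    )


def _region_positions(region: RegionDef) -> list[int]:
    return [n for lo, hi in region.ranges for n in range(lo, hi + 1)]


def mutate(peptide: PeptideRecord, position: int, to: str) -> PeptideRecord:
    """Point substitution at an author-numbered position of the source region
    (1-based index when the peptide has no structural source)."""
    to = to.upper()
    if to not in STANDARD_AA:
        raise SequenceError(f"unknown amino acid {to!r}")
    if peptide.source is not None:
        positions = _region_positions(peptide.source)
        if position not in positions:
            raise ConfigError(
                f"position {position} outside region {peptide.source.name}"
            )
        index = positions.index(position)
    else:
        if not 1 <= position <= len(peptide.sequence):
            raise ConfigError(f"position {position} outside 1..{len(peptide.sequence)}")
        index = position - 1
    old = peptide.sequence[index]
    seq = peptide.sequence[:index] + to + peptide.sequence[index + 1:]
    return replace(
        peptide,
        sequence=seq,
        mutations=peptide.mutations + ((position, old, to),),
    )


def cyclize(peptide: PeptideRecord, name: str | None = None) -> PeptideRecord:
    """Add terminal cysteines (disulfide-closed head-to-tail mimetic)."""
    if peptide.cyclic:
        raise SequenceError(f"{peptide.name} is already cyclic")
    return replace(
        peptide,
        name=name or f"{peptide.name}-cyc",
        sequence="C" + peptide.sequence + "C",
        cyclic=True,
    )


# ---------------------------------------------------------------------------
# Physicochemical panel
# ---------------------------------------------------------------------------

def molecular_weight(sequence: str) -> float:
    """Average-isotopic molecular weight (Da): residue masses + one water."""
    sequence = _check_sequence(sequence)
    return sum(RESIDUE_MASS[c] for c in sequence) + WATER_MASS


def charge_at_ph(sequence: str, ph: float) -> float:
    """Modeled net charge at a given pH (Henderson–Hasselbalch, Bjellqvist pKas)."""
    sequence = _check_sequence(sequence)

    def positive(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def negative(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = positive(PKA_NTERM.get(sequence[0], PKA_NTERM_DEFAULT))
    charge += negative(PKA_CTERM.get(sequence[-1], PKA_CTERM_DEFAULT))
    for letter in sequence:
        if letter in PKA_POSITIVE_SIDE:
            charge += positive(PKA_POSITIVE_SIDE[letter])
        elif letter in PKA_NEGATIVE_SIDE:
            charge += negative(PKA_NEGATIVE_SIDE[letter])
    return charge


def isoelectric_point(sequence: str, tolerance: float = 0.0005) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if charge_at_ph(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def net_charge(sequence: str) -> int:
    """Integer formal charge at pH 7: (#K + #R) − (#D + #E)."""
    sequence = _check_sequence(sequence)
    return (sequence.count("K") + sequence.count("R")
            - sequence.count("D") - sequence.count("E"))


# ---------------------------------------------------------------------------
# Protease cleavage rules (PeptideCutter matrices)
# ---------------------------------------------------------------------------
#
# A rule decides whether the bond C-terminal to residue i is cleaved from the
# local window P4..P2'.  Window positions outside the sequence satisfy
# negative ("not in") constraints and fail positive ("in") constraints; with
# terminal counting enabled (the default) the bond after the final residue
# therefore counts whenever only negative constraints apply beyond it.

RuleFn = Callable[[Callable[[int], str | None]], bool]


def _notin(c: str | None, cls: str) -> bool:
    return c is None or c not in cls


def _isin(c: str | None, cls: str) -> bool:
    return c is not None and c in cls


def _rule_trypsin(w: Callable[[int], str | None]) -> bool:
    p2, p1, q1 = w(-1), w(0), w(1)
    if p1 not in ("K", "R"):
        return False
    if _isin(q1, "P"):
        # proline block, lifted by the WKP / MRP exceptions
        return (p2 == "W" and p1 == "K") or (p2 == "M" and p1 == "R")
    if p1 == "K" and ((_isin(p2, "CD") and q1 == "D") or (p2 == "C" and _isin(q1, "HY"))):
        return False
    if p1 == "R" and ((p2 == "C" and q1 == "K") or (p2 == "R" and _isin(q1, "HR"))):
        return False
    return True


def _rule_chymotrypsin_high(w) -> bool:
    p1, q1 = w(0), w(1)
    if p1 in ("F", "Y"):
        return _notin(q1, "P")
    if p1 == "W":
        return _notin(q1, "MP")
    return False


def _rule_chymotrypsin_low(w) -> bool:
    p1, q1 = w(0), w(1)
    if p1 in ("F", "L", "Y"):
        return _notin(q1, "P")
    if p1 == "W":
        return _notin(q1, "MP")
    if p1 == "M":
        return _notin(q1, "PY")
    if p1 == "H":
        return _notin(q1, "DMPW")
    return False


def _pepsin_rule(p1_prime_class: str) -> RuleFn:
    def rule(w: Callable[[int], str | None]) -> bool:
        p3, p2, p1, q1, q2 = w(-2), w(-1), w(0), w(1), w(2)
        if not (_notin(p3, "HKR") and _notin(p2, "P")):
            return False
        clause_a = _notin(p1, "R") and _isin(q1, p1_prime_class) and _notin(q2, "P")
        clause_b = _isin(p1, p1_prime_class) and q1 is not None and _notin(q2, "P")
        return clause_a or clause_b

    return rule


@dataclass
class CleavageRuleSet:
    """Deterministic local-window cleavage rules, one per enzyme."""

    rules: Mapping[str, RuleFn] = field(default_factory=lambda: dict(DEFAULT_RULES))
    terminal_counting: bool = True

    def enzymes(self) -> list[str]:
        return list(self.rules)


DEFAULT_RULES: dict[str, RuleFn] = {
    "trypsin": _rule_trypsin,
    "chymotrypsin_high": _rule_chymotrypsin_high,
    "chymotrypsin_low": _rule_chymotrypsin_low,
    "pepsin_1.3": _pepsin_rule("FL"),
    "pepsin_gt2": _pepsin_rule("FLWY"),
}


def cleavage_sites(
    sequence: str,
    enzyme: str,
    rules: CleavageRuleSet | None = None,
) -> tuple[int, list[int]]:
    """Count and 1-based positions i such that the bond C-terminal to residue
    i is cleaved by the enzyme's rule."""
    rules = rules or CleavageRuleSet()
    sequence = _check_sequence(sequence)
    if enzyme not in rules.rules:
        raise ConfigError(
            f"unknown enzyme {enzyme!r}; known: {sorted(rules.rules)}"
        )
    rule = rules.rules[enzyme]
    last = len(sequence) if rules.terminal_counting else len(sequence) - 1
    sites = []
    for i in range(last):
        def window(offset: int, i: int = i) -> str | None:
            j = i + offset
            return sequence[j] if 0 <= j < len(sequence) else None

        if rule(window):
            sites.append(i + 1)
    return len(sites), sites


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def physchem_profile(sequence: str, rules: CleavageRuleSet | None = None) -> dict:
    rules = rules or CleavageRuleSet()
    profile = {
        "mw": round(molecular_weight(sequence), 2),
        "pi": round(isoelectric_point(sequence), 2),
        "net_charge": net_charge(sequence),
    }
    for enzyme in rules.enzymes():
        profile[f"sites_{enzyme}"] = cleavage_sites(sequence, enzyme, rules)[0]
    return profile


def design_report(
    peptides: Sequence[PeptideRecord], rules: CleavageRuleSet | None = None
) -> pd.DataFrame:
    """One row per peptide: sequence, cyclic flag, MW, pI, net charge and
    per-enzyme cleavage counts.  Row order follows the input order."""
    rules = rules or CleavageRuleSet()
    cols = ["name", "sequence", "cyclic", "mw", "pi", "net_charge"] + [
        f"sites_{e}" for e in rules.enzymes()
    ]
    rows = []
    for pep in peptides:
        row = {"name": pep.name, "sequence": pep.sequence, "cyclic": pep.cyclic}
        row.update(physchem_profile(pep.sequence, rules))
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)
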