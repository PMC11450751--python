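"""Aggregation of pair interaction energies into hot-spot profiles.

Per-residue totals, per-region (CDR) totals, fractional contributions to the
total binding energy, cumulative energy–distance profiles, and hot-spot
rankings.  The shipped region defaults are the three CDRs that dominate the
aducanumab::Aβ2–7 interface: HCDR2 (heavy chain 50–60), HCDR3 (heavy chain
101–109) and LCDR3 (light chain 90–96).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mfcc import InteractionRecord
from .structures import ResidueRef


@dataclass(frozen=True)
class RegionDef:
    """A named set of inclusive author-numbered intervals on one chain."""

    name: str
    chain_id: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for lo, hi in self.ranges:
            span = set(range(lo, hi + 1))
            if covered & span:
                raise ConfigError(f"region {self.name}: overlapping intervals")
            covered |= span

    def contains(self, ref: ResidueRef) -> bool:
        return ref.chain_id == self.chain_id and any(
            lo <= ref.seq_number <= hi for lo, hi in self.ranges
        )


DEFAULT_CDRS: tuple[RegionDef, ...] = (
    RegionDef("HCDR2", "H", ((50, 60),)),
    RegionDef("HCDR3", "H", ((101, 109),)),
    RegionDef("LCDR3", "L", ((90, 96),)),
)

OTHER = "other"


def per_residue_totals(
    records: Sequence[InteractionRecord], side: str = "a"
) -> dict[ResidueRef, float]:
    """Sum each residue's pair energies on one side of the interface."""
    if side not in ("a", "b"):
        raise ConfigError("side must be 'a' or 'b'")
    idx = 0 if side == "a" else 1
    totals: dict[ResidueRef, float] = {}
    for rec in records:
        ref = rec.pair[idx]
        totals[ref] = totals.get(ref, 0.0) + rec.energy
    return totals


def region_totals(
    per_residue: Mapping[ResidueRef, float],
    regions: Sequence[RegionDef] = DEFAULT_CDRS,
) -> dict[str, float]:
    """Sum per-residue energies into named regions; residues outside every
    region are reported under ``other``."""
    for i, ra in enumerate(regions):
        for rb in regions[i + 1:]:
            if ra.chain_id == rb.chain_id:
                span_a = {n for lo, hi in ra.ranges for n in range(lo, hi + 1)}
                span_b = {n for lo, hi in rb.ranges for n in range(lo, hi + 1)}
                if span_a & span_b:
                    raise ConfigError(f"regions {ra.name} and {rb.name} overlap")
    totals = {r.name: 0.0 for r in regions}
    totals[OTHER] = 0.0
    for ref, energy in per_residue.items():
        for region in regions:
            if region.contains(ref):
                totals[region.name] += energy
                break
        else:
            totals[OTHER] += energy
    return totals


def fraction_of_total(
    region_totals_: Mapping[str, float], total: float
) -> dict[str, float]:
    """Each region's share of the total, as a percentage."""
    if total == 0:
        raise ZeroDivisionError("total interaction energy is zero")
    return {name: 100.0 * value / total for name, value in region_totals_.items()}


@dataclass
class CumulativeProfile:
    """Cumulative interaction energy as a function of the pair-distance cutoff."""

    cutoffs: np.ndarray  # Å
    values: np.ndarray   # kcal/mol

    def value_at(self, r: float) -> float:
        i = int(np.searchsorted(self.cutoffs, r, side="right")) - 1
        return float(self.values[i]) if i >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff_A": self.cutoffs, "cumulative_kcal_mol": self.values})


def cumulative_profile(
    records: Sequence[InteractionRecord],
    grid: Sequence[float] | None = None,
) -> CumulativeProfile:
    """value(r) = sum of pair energies with pair_distance ≤ r (default grid
    0 → 8 Å in 0.25 Å steps)."""
    cutoffs = (np.arange(0.0, 8.0 + 1e-9, 0.25) if grid is None
               else np.asarray(list(grid), dtype=float))
    values = np.array([
        sum(rec.energy for rec in records if rec.pair_distance <= r)
        for r in cutoffs
    ])
    return CumulativeProfile(cutoffs, values)


def rank_hotspots(
    per_residue: Mapping[ResidueRef, float], k: int | None = None
) -> list[tuple[ResidueRef, float]]:
    """Residues sorted most-attractive first (ascending energy); ties broken
    by (chain, seq_number)."""
    if k is not None and k < 1:
        raise ConfigError("k must be >= 1")
    ranked = sorted(
        per_residue.items(),
        key=lambda kv: (kv[1], kv[0].chain_id, kv[0].seq_number, kv[0].insertion_code),
    )
    return ranked if k is None else ranked[:k]


@dataclass
class HotspotReport:
    per_residue: dict[ResidueRef, float]
    per_region: dict[str, float]
    total: float
    fractions: dict[str, float]
    profile: CumulativeProfile | None = None
    ranking: list[tuple[ResidueRef, float]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "total_kcal_mol": self.total,
            "per_residue": {str(ref): e for ref, e in self.per_residue.items()},
            "per_region": self.per_region,
            "fractions_percent": {k: round(v, 1) for k, v in self.fractions.items()},
            "ranking": [
                {"residue": str(ref), "energy_kcal_mol": e} for ref, e in self.ranking
            ],
        }
        if self.profile is not None:
            payload["profile"] = {
                "cutoff_A": self.profile.cutoffs.tolist(),
                "cumulative_kcal_mol": self.profile.values.tolist(),
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def hotspot_report(
    records: Sequence[InteractionRecord],
    regions: Sequence[RegionDef] = DEFAULT_CDRS,
    side: str = "a",
    grid: Sequence[float] | None = None,
) -> HotspotReport:
    """Full aggregation of one interface-energy run."""
    per_res = per_residue_totals(records, side=side)
    per_reg = region_totals(per_res, regions)
    total = float(sum(rec.energy for rec in records))
    fractions = fraction_of_total(per_reg, total) if total != 0 else {}
    return HotspotReport(
        per_residue=per_res,
        per_region=per_reg,
        total=total,
        fractions=fractions,
        profile=cumulative_profile(records, grid),
        ranking=rank_hotspots(per_res),
    )


# ---------------------------------------------------------------------------
# Per-residue energy tables (for ingesting externally computed values)
# ---------------------------------------------------------------------------

def read_per_residue_csv(path: str | Path) -> dict[ResidueRef, float]:
    """Read a per-residue energy table (columns: chain, seq_number, res_name,
    energy_kcal_mol) into a per-residue map."""
    frame = pd.read_csv(path)
    required = {"chain", "seq_number", "res_name", "energy_kcal_mol"}
    if not required.issubset(frame.columns):
        raise ConfigError(f"per-residue table must have columns {sorted(required)}")
    return {
        ResidueRef(str(r.chain), int(r.seq_number), "", str(r.res_name)):
            float(r.energy_kcal_mol)
        for r in frame.itertuples()
    }


def write_per_residue_csv(
    per_residue: Mapping[ResidueRef, float], path: str | Path
) -> None:
    rows = [
        {"chain": ref.chain_id, "seq_number": ref.seq_number,
         "res_name": ref.res_name, "energy_kcal_mol": e}
        for ref, e in per_residue.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
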