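"""End-to-end orchestration with a validated config and a run manifest.

Stages run in the workflow's natural order — ensemble descriptors, contact
detection, MFCC interface energies, hot-spot aggregation, peptide design —
and every output file is listed in a manifest with input hashes, the seed
and the package version, so a rerun with an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .contacts import (
    ContactCriteria,
    conservation,
    contacts_to_frame,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
)
from .ensemble import extract_representatives, featurize, rmsd_series, rmsf_per_residue, select_representatives
from .errors import ConfigError, EpitopeDecompError
from .mfcc import BackendConfig, interface_energies, records_to_frame, total_energy
from .peptides import cyclize, design_report, extract_segment
from .profiles import DEFAULT_CDRS, RegionDef, hotspot_report
from .structures import Trajectory, read_pdb, write_pdb

log = logging.getLogger("epitope_decomp")


class CriteriaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hbond_ha_max: float = 2.70
    hbond_da_max: float = 3.35
    hydrophobic_min: float = 2.90
    hydrophobic_max: float = 3.90
    salt_bridge_max: float = 4.00


class BackendSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "classical"
    dielectric: float = 40.0
    table_path: str | None = None


class RegionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    chain: str
    ranges: list[tuple[int, int]]


class EnsembleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    k_min: int = 2
    k_max: int = 10
    reduce: bool = False


class PeptideSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    cyclize: bool = True


class RunConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    input_pdb: str
    outdir: str
    group_a: list[str]
    group_b: list[str]
    keep_waters: bool = True
    cutoff: float = 8.0
    water_shell: float | None = None
    seed: int = 0
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    backend: BackendSection = Field(default_factory=BackendSection)
    regions: list[RegionSection] = Field(default_factory=list)
    ensemble: EnsembleSection = Field(default_factory=EnsembleSection)
    peptides: PeptideSection = Field(default_factory=PeptideSection)

    @field_validator("group_b")
    @classmethod
    def _no_overlap(cls, v, info):
        if info.data.get("group_a") and set(v) & set(info.data["group_a"]):
            raise ValueError("group_a and group_b overlap")
        return v

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.model_validate(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(EpitopeDecompError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
        return wrap

    criteria = ContactCriteria(**config.criteria.model_dump())
    regions = [RegionDef(r.name, r.chain, tuple(tuple(t) for t in r.ranges))
               for r in config.regions]
    chain_pair = (config.group_a, config.group_b)
    state: dict = {}

    @stage("read")
    def _read():
        models = read_pdb(config.input_pdb, keep_waters=config.keep_waters)
        state["models"] = models
        state["structure"] = models[0]

    @stage("contacts")
    def _contacts():
        per_model = []
        for model in state["models"]:
            mode = "with_hydrogens" if model.has_hydrogens() else "heavy_only"
            recs = (detect_hbonds(model, chain_pair, criteria, mode=mode)
                    + detect_hydrophobic(model, chain_pair, criteria)
                    + detect_salt_bridges(model, chain_pair, criteria))
            per_model.append(recs)
        path = outdir / "contacts.csv"
        contacts_to_frame(per_model[0]).to_csv(path, index=False)
        outputs["contacts"] = path
        if len(per_model) > 1:
            summary = conservation(per_model)
            cons = outdir / "conservation.json"
            cons.write_text(json.dumps(
                {"n_conformations": summary.n_conformations,
                 "counts": {" | ".join(k): v for k, v in sorted(summary.counts.items())}},
                indent=2))
            outputs["conservation"] = cons

    @stage("mfcc")
    def _mfcc():
        backend = BackendConfig(
            kind=config.backend.kind,
            dielectric=config.backend.dielectric,
            table_path=config.backend.table_path,
        ).resolve()
        records = interface_energies(
            state["structure"], config.group_a, config.group_b,
            backend, cutoff=config.cutoff, water_shell=config.water_shell,
        )
        state["records"] = records
        path = outdir / "energies.csv"
        records_to_frame(records).to_csv(path, index=False)
        outputs["energies"] = path
        log.info("interface total: %.3f kcal/mol over %d pairs",
                 total_energy(records), len(records))

    @stage("hotspots")
    def _hotspots():
        report = hotspot_report(state["records"],
                                regions if regions else DEFAULT_CDRS, side="a")
        path = outdir / "hotspots.json"
        report.to_json(path)
        outputs["hotspots"] = path
        profile_path = outdir / "profile.csv"
        report.profile.to_frame().to_csv(profile_path, index=False)
        outputs["profile"] = profile_path

    if config.ensemble.enabled:
        @stage("ensemble")
        def _ensemble():
            traj = Trajectory(state["models"])
            feats = featurize(traj)
            model = select_representatives(
                feats, (config.ensemble.k_min, config.ensemble.k_max),
                reduce=config.ensemble.reduce, seed=config.seed,
            )
            path = outdir / "ensemble.json"
            path.write_text(json.dumps({
                "n_clusters": model.n_clusters,
                "labels": model.labels.tolist(),
                "representatives": model.representatives,
                "silhouette_by_k": model.silhouette_by_k,
                "rmsd": rmsd_series(traj).tolist(),
                "rmsf": {str(k): v for k, v in rmsf_per_residue(traj).items()},
            }, indent=2))
            outputs["ensemble"] = path
            reps = outdir / "representatives.pdb"
            write_pdb(extract_representatives(traj, model), reps)
            outputs["representatives"] = reps

    if config.peptides.enabled:
        @stage("peptides")
        def _peptides():
            peps = []
            for region in regions:
                linear = extract_segment(state["structure"], region,
                                         name=f"{region.name}-L")
                peps.append(linear)
                if config.peptides.cyclize:
                    peps.append(cyclize(linear, name=f"{region.name}-C"))
            path = outdir / "peptides.csv"
            design_report(peps).to_csv(path, index=False)
            outputs["peptides"] = path

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "inputs": {config.input_pdb: _sha256(Path(config.input_pdb))},
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
        "timings_s": timings,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
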