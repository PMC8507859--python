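"""End-to-end orchestration of the four-stage workflow.

Stages: (i) conformer selection by adaptive gromos clustering of each
peptide's conformational ensemble; (ii) localization of docked poses on
the receptor (PAM clustering of centers of mass + region assignment);
(iii) per-residue contact profiling of each pose ensemble against the
zone of interest; (iv) statistical training (key-residue derivation from
active vs inactive peptides) and activity prediction for query peptides.

A :class:`PipelineConfig` (usually loaded from YAML) names the receptor,
the region definitions, and per-ligand inputs at whatever granularity is
available: a conformer ensemble (stage i), pose ensembles (stages ii-iii),
or precomputed contact-profile tables (straight to stage iv).  All report
files are deterministic for a fixed seed and config — no timestamps, fixed
ordering — so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conformer_clustering import ClusteringConfig, cluster_ensemble
from .contact_profiling import ContactConfig, ContactProfile, profile_ensemble
from .discrim_stats import (
    ActivityCall,
    KeyResidueSet,
    StatsConfig,
    compare_profiles,
    derive_key_residues,
    predict_activity,
)
from .pose_regions import RegionDefinition, ResidueKey, load_regions, localize_poses
from .structure_io import read_multimodel_pdb

logger = logging.getLogger("pepsurf")

VALID_CLASSES = ("active", "inactive", "query")


@dataclass
class LigandInputs:
    label: str
    ligand_class: str                       # active / inactive / query
    conformers: Path | None = None          # multi-model PDB of MD snapshots
    poses: list[Path] = field(default_factory=list)    # one pose PDB per conformer
    profiles: list[Path] = field(default_factory=list) # precomputed contact TSVs

    def __post_init__(self):
        if self.ligand_class not in VALID_CLASSES:
            raise ValueError(
                f"ligand {self.label!r}: class must be one of {VALID_CLASSES}"
            )


@dataclass
class PipelineConfig:
    receptor: Path | None
    regions_file: Path | None
    ligands: list[LigandInputs]
    zone_name: str = "catalytic"
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    pam_k: int | None = None
    pam_k_range: tuple[int, int] = (2, 8)
    region_max_dist: float = 15.0
    seed: int = 0

    def __post_init__(self):
        labels = [l.label for l in self.ligands]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ligand labels in config")

    def by_class(self, ligand_class: str) -> list[LigandInputs]:
        return [l for l in self.ligands if l.ligand_class == ligand_class]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return (base / p) if p is not None else None

        ligands = []
        for label, spec in data.get("ligands", {}).items():
            ligands.append(
                LigandInputs(
                    label=label,
                    ligand_class=spec["class"],
                    conformers=resolve(spec.get("conformers")),
                    poses=[resolve(p) for p in spec.get("poses", [])],
                    profiles=[resolve(p) for p in spec.get("profiles", [])],
                )
            )
        return cls(
            receptor=resolve(data.get("receptor")),
            regions_file=resolve(data.get("regions")),
            ligands=ligands,
            zone_name=data.get("zone", "catalytic"),
            clustering=ClusteringConfig(**data.get("clustering", {})),
            contacts=ContactConfig(**data.get("contacts", {})),
            stats=StatsConfig(**data.get("stats", {})),
            pam_k=data.get("pam_k"),
            pam_k_range=tuple(data.get("pam_k_range", (2, 8))),
            region_max_dist=float(data.get("region_max_dist", 15.0)),
            seed=int(data.get("seed", 0)),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _residue_sort_key(r: ResidueKey):
    return (r.chain_id, r.residue_seq)


class Pipeline:
    """Stateful runner holding loaded inputs and intermediate products."""

    def __init__(self, config: PipelineConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.receptor = None
        self.regions: list[RegionDefinition] = []
        self.zone: RegionDefinition | None = None
        self.profiles: dict[str, list[ContactProfile]] = {}
        self._load_receptor()

    def _load_receptor(self) -> None:
        cfg = self.config
        if cfg.receptor is not None:
            self.receptor = read_multimodel_pdb(cfg.receptor, label="receptor")[0]
        if cfg.regions_file is not None:
            self.regions = load_regions(cfg.regions_file)
            zones = [r for r in self.regions if r.region_name == cfg.zone_name]
            if not zones:
                raise ValueError(f"zone {cfg.zone_name!r} not found in region file")
            self.zone = zones[0]

    # --- stages ---------------------------------------------------------

    def stage_conformers(self) -> dict[str, dict]:
        """Cluster each ligand's conformer ensemble; report representatives."""
        reports = {}
        for lig in self.config.ligands:
            if lig.conformers is None:
                continue
            t0 = time.perf_counter()
            ensemble = read_multimodel_pdb(lig.conformers, label=lig.label)
            result = cluster_ensemble(ensemble, self.config.clustering)
            report = {
                "ligand": lig.label,
                "n_models": len(ensemble),
                "cutoff_used": result.cutoff_used,
                "coverage_warning": result.coverage_warning,
                "clusters": [
                    {"center": c.center, "size": len(c), "fraction": round(c.fraction, 6)}
                    for c in result.clusters
                ],
                "representatives": result.representative_indices,
            }
            reports[lig.label] = report
            _write_json(self.outdir / f"conformers_{lig.label}.json", report)
            logger.info(
                "conformers[%s]: %d clusters at %.1f A (%.2fs)",
                lig.label, len(result.clusters), result.cutoff_used,
                time.perf_counter() - t0,
            )
        return reports

    def stage_localization(self) -> dict[str, list[dict]]:
        """Localize each ligand's pose ensembles on the receptor regions."""
        if self.receptor is None or not self.regions:
            return {}
        reports: dict[str, list[dict]] = {}
        for lig in self.config.ligands:
            for i, pose_path in enumerate(lig.poses):
                t0 = time.perf_counter()
                poses = read_multimodel_pdb(pose_path, label=lig.label)
                loc = localize_poses(
                    poses, self.receptor, self.regions,
                    k=self.config.pam_k, k_range=self.config.pam_k_range,
                    max_dist=self.config.region_max_dist,
                )
                rows = [
                    {
                        "region": region,
                        "n_poses": int(round(frac * len(poses))),
                        "fraction": round(frac, 6),
                    }
                    for region, frac in sorted(loc.occupancy.items())
                ]
                pd.DataFrame(rows).to_csv(
                    self.outdir / f"localization_{lig.label}_{i}.tsv", sep="\t", index=False
                )
                reports.setdefault(lig.label, []).append(
                    {"occupancy": {r["region"]: r["fraction"] for r in rows}}
                )
                logger.info(
                    "localization[%s/%d]: %s (%.2fs)", lig.label, i,
                    {r["region"]: r["fraction"] for r in rows},
                    time.perf_counter() - t0,
                )
        return reports

    def stage_profiles(self) -> dict[str, list[ContactProfile]]:
        """Obtain contact profiles per ligand: from TSVs or from poses."""
        profiles: dict[str, list[ContactProfile]] = {}
        for lig in self.config.ligands:
            lig_profiles: list[ContactProfile] = []
            for path in lig.profiles:
                lig_profiles.append(ContactProfile.from_tsv(path, ligand_label=lig.label))
            if not lig_profiles and lig.poses:
                if self.receptor is None or self.zone is None:
                    raise ValueError(
                        f"ligand {lig.label!r} supplies poses but no receptor/zone is configured"
                    )
                for pose_path in lig.poses:
                    poses = read_multimodel_pdb(pose_path, label=lig.label)
                    lig_profiles.append(
                        profile_ensemble(self.receptor, poses, self.zone, self.config.contacts)
                    )
            if not lig_profiles:
                raise ValueError(
                    f"ligand {lig.label!r} has neither profiles nor poses: "
                    "no contact data for the statistical stage"
                )
            for i, prof in enumerate(lig_profiles):
                prof.to_tsv(self.outdir / f"profile_{lig.label}_{i}.tsv")
            profiles[lig.label] = lig_profiles
        self.profiles = profiles
        return profiles

    def stage_training(self) -> KeyResidueSet:
        """Pairwise comparisons + key-residue derivation; writes reports."""
        actives = {l.label: self.profiles[l.label] for l in self.config.by_class("active")}
        inactives = {l.label: self.profiles[l.label] for l in self.config.by_class("inactive")}
        if not actives:
            raise ValueError("training requires >=1 active ligand")
        if not inactives:
            raise ValueError("training requires >=1 inactive ligand")
        rows = []
        for a_label, a_profiles in sorted(actives.items()):
            for i_label, i_profiles in sorted(inactives.items()):
                for ca, pa in enumerate(a_profiles):
                    for ci, pb in enumerate(i_profiles):
                        comp = compare_profiles(pa, pb, self.config.stats)
                        for r, t, p, d, f in zip(
                            comp.residues, comp.t, comp.p, comp.mean_diff,
                            comp.significant_higher,
                        ):
                            rows.append(
                                {
                                    "active": a_label, "active_conformer": ca,
                                    "inactive": i_label, "inactive_conformer": ci,
                                    "residue": str(r), "t": round(float(t), 6),
                                    "p": round(float(p), 9),
                                    "mean_diff": round(float(d), 6),
                                    "significant_higher": bool(f),
                                }
                            )
        pd.DataFrame(rows).to_csv(self.outdir / "comparisons.tsv", sep="\t", index=False)
        key_set = derive_key_residues(actives, inactives, self.config.stats)
        _write_json(
            self.outdir / "key_residues.json",
            {
                "residues": [str(r) for r in sorted(key_set.residues, key=_residue_sort_key)],
                "short": key_set.short_names(),
                "provenance": {
                    lab: [str(r) for r in sorted(res, key=_residue_sort_key)]
                    for lab, res in sorted(key_set.provenance.items())
                },
            },
        )
        logger.info("training: key residues = %s", key_set.short_names())
        return key_set

    def stage_prediction(self, key_set: KeyResidueSet) -> dict[str, ActivityCall]:
        actives = {l.label: self.profiles[l.label] for l in self.config.by_class("active")}
        calls = {}
        for lig in self.config.by_class("query"):
            call = predict_activity(
                self.profiles[lig.label], actives, key_set, self.config.stats
            )
            calls[lig.label] = call
            _write_json(
                self.outdir / f"activity_{lig.label}.json",
                {
                    "query": call.query_label,
                    "decision": call.decision,
                    "differing_key_residues": {
                        a: [str(r) for r in sorted(res, key=_residue_sort_key)]
                        for a, res in sorted(call.differing.items())
                    },
                    "rationale": call.rationale,
                },
            )
            logger.info("prediction[%s]: %s", lig.label, call.decision)
        return calls


def run_training(config: PipelineConfig, outdir: str | Path) -> KeyResidueSet:
    """Stages i-iv (training): returns the derived key-residue set."""
    pipe = Pipeline(config, outdir)
    for stage_name, stage in (
        ("conformer-clustering", pipe.stage_conformers),
        ("pose-localization", pipe.stage_localization),
        ("contact-profiling", pipe.stage_profiles),
    ):
        try:
            stage()
        except Exception as exc:
            raise StageError(stage_name, exc) from exc
    try:
        return pipe.stage_training()
    except Exception as exc:
        raise StageError("training", exc) from exc


def run_prediction(
    config: PipelineConfig, key_set: KeyResidueSet, outdir: str | Path
) -> dict[str, ActivityCall]:
    """Activity prediction for every query ligand in the config."""
    pipe = Pipeline(config, outdir)
    try:
        pipe.stage_profiles()
        return pipe.stage_prediction(key_set)
    except Exception as exc:
        raise StageError("prediction", exc) from exc


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Full workflow: training plus prediction for query ligands.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    pipe = Pipeline(config, outdir)
    for stage_name, stage in (
        ("conformer-clustering", pipe.stage_conformers),
        ("pose-localization", pipe.stage_localization),
        ("contact-profiling", pipe.stage_profiles),
    ):
        try:
            stage()
        except Exception as exc:
            raise StageError(stage_name, exc) from exc
    try:
        key_set = pipe.stage_training()
        calls = pipe.stage_prediction(key_set)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("training/prediction", exc) from exc
    summary = {
        "key_residues": key_set.short_names(),
        "predictions": {label: call.decision for label, call in sorted(calls.items())},
        "seed": config.seed,
    }
    _write_json(outdir / "summary.json", summary)
    return summary
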