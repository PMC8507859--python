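"""Synthetic fixtures for the docking post-processing pipeline.

Real inputs to this pipeline are a molecular-dynamics conformer ensemble,
a docked-pose ensemble (the 100 best rigid-docking solutions) and the
MMP-14 catalytic domain.  None of those can be regenerated at desk scale,
so this module produces structurally valid stand-ins with *known ground
truth*, which the rest of the package treats exactly like real data:

* conformer ensembles with planted conformational classes (template
  structures plus iid Gaussian coordinate jitter and a random rigid
  motion per snapshot), with the planted labels returned for recovery
  tests;
* a synthetic receptor whose residue numbering and names reproduce the
  MMP-14 catalytic-zone definition, plus an MT-Loop-like region placed
  30 A away, so region assignment and contact counting run unchanged;
* pose ensembles whose centers of mass are drawn from a region-anchored
  Gaussian mixture with known weights;
* contact-count profiles with class-specific per-residue means/SDs for
  the statistical screen.

All randomness flows through ``numpy.random.Generator`` (PCG64); a fixed
integer seed reproduces every fixture bit for bit.  The peptide sequences
studied against MMP-14 ship as live fixtures (idealized C-alpha traces).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .contact_profiling import ContactProfile
from .pose_regions import (
    CATALYTIC_ZONE_RESIDUES,
    RegionDefinition,
    ResidueKey,
)
from .structure_io import Atom, Ensemble, StructureModel, center_of_mass, rmsd_after_fit

#: Lumican-derived peptides and their SLRP analogues, with known activity
#: against MMP-14 where established (the query peptide L9Mc is the cyclic
#: form of L9M, flanked by two cysteines).
PEPTIDE_SEQUENCES: dict[str, str] = {
    "lumcorin": "SSLVELDLSYNKLKNIP",
    "L9M": "ELDLSYNKLK",
    "L9Mc": "CELDLSYNKLKC",
    "D9M": "ELHLDNNKLT",
    "F9M": "ELDLSYNQLQ",
}

PEPTIDE_ACTIVITY: dict[str, str] = {
    "lumcorin": "active",
    "L9M": "active",
    "D9M": "inactive",
    "F9M": "inactive",
    "L9Mc": "query",
}

_THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

_CA_SPACING = 3.8  # A, consecutive C-alpha distance in an extended chain


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def peptide_ca_template(label: str, sequence: str | None = None, chain_id: str = "P") -> StructureModel:
    """Idealized extended C-alpha trace of a peptide sequence.

    Consecutive alpha-carbons are 3.8 A apart along a shallow zig-zag, the
    geometry of a fully extended chain reduced to its trace.  ``label`` may
    be one of :data:`PEPTIDE_SEQUENCES`; otherwise ``sequence`` is required.
    """
    if sequence is None:
        try:
            sequence = PEPTIDE_SEQUENCES[label]
        except KeyError:
            raise KeyError(f"unknown peptide {label!r}; pass an explicit sequence") from None
    atoms = []
    for i, letter in enumerate(sequence.upper()):
        if letter not in _THREE_LETTER:
            raise ValueError(f"unknown amino-acid letter {letter!r} in {label}")
        x = i * _CA_SPACING * np.cos(np.pi / 12)
        y = (_CA_SPACING * np.sin(np.pi / 12)) * (i % 2)
        atoms.append(
            Atom(
                serial=i + 1, name="CA", element="C",
                residue_name=_THREE_LETTER[letter], chain_id=chain_id,
                residue_seq=i + 1, coords=np.array([x, y, 0.0]),
            )
        )
    return StructureModel(1, atoms)


# --- conformer ensembles -----------------------------------------------------

def make_conformer_templates(
    base: StructureModel,
    n_conformers: int,
    separation: float,
    rng: int | np.random.Generator,
) -> list[StructureModel]:
    """Shape-distinct templates with pairwise post-fit RMSD >= ``separation``.

    Each template is the base structure plus a random smooth deformation;
    displacements are rescaled until every template pair is at least
    ``separation`` apart after superposition (rigid motion cannot mask the
    difference).
    """
    rng = _rng(rng)
    n_atoms = len(base)
    base_coords = base.coords
    displacements = rng.normal(size=(n_conformers, n_atoms, 3))
    displacements[0] = 0.0  # first conformer is the base itself
    scale = separation
    for _ in range(60):
        templates = [
            base.with_coords(base_coords + scale * d, model_id=i + 1)
            for i, d in enumerate(displacements)
        ]
        min_rmsd = min(
            rmsd_after_fit(templates[i], templates[j], selection=None)
            for i in range(n_conformers)
            for j in range(i + 1, n_conformers)
        ) if n_conformers > 1 else np.inf
        if min_rmsd >= separation:
            return templates
        scale *= 1.3
    raise RuntimeError("could not separate conformer templates; increase atom count")


def gen_conformer_ensemble(
    templates: Sequence[StructureModel],
    fractions: Sequence[float],
    n_models: int,
    jitter_sd: float,
    rng: int | np.random.Generator,
    label: str = "synthetic",
    random_rigid: bool = True,
) -> tuple[Ensemble, np.ndarray]:
    """Multi-model ensemble with planted conformational classes.

    Population fractions are honored exactly (rounded to counts), the model
    order is shuffled, and each model receives iid Gaussian coordinate
    jitter of ``jitter_sd`` plus (by default) a random rigid motion, so
    that recovery requires RMSD fitting.  Returns the ensemble and the
    planted class label of each model.
    """
    rng = _rng(rng)
    fractions = np.asarray(fractions, dtype=float)
    if len(templates) != len(fractions) or len(templates) == 0:
        raise ValueError("need one population fraction per template")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("population fractions must sum to 1")
    ref = templates[0].identities()
    for t in templates[1:]:
        if t.identities() != ref:
            raise ValueError("conformer templates must share atom identities")
    counts = np.floor(fractions * n_models).astype(int)
    for i in np.argsort(-(fractions * n_models - counts))[: n_models - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(templates)), counts)
    rng.shuffle(labels)
    models = []
    for mi, lab in enumerate(labels):
        coords = templates[lab].coords + rng.normal(scale=jitter_sd, size=(len(ref), 3))
        if random_rigid:
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, size=3)
            coords = coords @ R.T + t
        models.append(templates[lab].with_coords(coords, model_id=mi + 1))
    return Ensemble(models, label=label), labels


# --- synthetic receptor and regions -----------------------------------------

MT_LOOP_RESIDUES: tuple[tuple[int, str], ...] = (
    (163, "PRO"), (164, "TYR"), (165, "ALA"), (166, "TYR"), (167, "ILE"),
    (168, "ARG"), (169, "GLU"), (170, "GLY"),
)

_BACKBONE_OFFSETS = {
    "N": np.array([-0.8, 0.6, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.9, 0.5, 0.3]),
    "O": np.array([1.0, 1.2, -0.5]),
}
_BACKBONE_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

CATALYTIC_CENTER = np.array([0.0, 0.0, 0.0])
MT_LOOP_CENTER = np.array([30.0, 0.0, 0.0])
FAR_POINT = np.array([0.0, 60.0, 0.0])  # > 15 A from both regions


def gen_receptor(chain_id: str = "A") -> tuple[StructureModel, list[RegionDefinition]]:
    """Deterministic synthetic receptor with catalytic-zone and MT-Loop regions.

    The catalytic-zone residues carry the genuine MMP-14 numbering and
    names (so the built-in zone definition validates against it); an
    MT-Loop-like 8-residue region sits 30 A away; filler residues complete
    a plausible domain.  Four backbone atoms (N, CA, C, O) per residue.
    """
    residues: list[tuple[int, str, np.ndarray]] = []
    for i, (seq, name) in enumerate(CATALYTIC_ZONE_RESIDUES):
        angle = 2 * np.pi * i / len(CATALYTIC_ZONE_RESIDUES)
        center = CATALYTIC_CENTER + 5.0 * np.array([np.cos(angle), np.sin(angle), 0.2 * (i % 3)])
        residues.append((seq, name, center))
    for i, (seq, name) in enumerate(MT_LOOP_RESIDUES):
        angle = 2 * np.pi * i / len(MT_LOOP_RESIDUES)
        center = MT_LOOP_CENTER + 4.0 * np.array([np.cos(angle), 0.3, np.sin(angle)])
        residues.append((seq, name, center))
    used = {seq for seq, _, _ in residues}
    filler = [seq for seq in range(150, 271) if seq not in used]
    for i, seq in enumerate(filler):
        angle = 2 * np.pi * i / len(filler)
        center = np.array([15.0 + 12.0 * np.cos(angle), 12.0 * np.sin(angle), -12.0])
        residues.append((seq, "ALA", center))
    residues.sort(key=lambda r: r[0])
    atoms, serial = [], 1
    for seq, name, center in residues:
        for atom_name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(
                    serial=serial, name=atom_name,
                    element=_BACKBONE_ELEMENTS[atom_name], residue_name=name,
                    chain_id=chain_id, residue_seq=seq,
                    coords=center + _BACKBONE_OFFSETS[atom_name],
                )
            )
            serial += 1
    receptor = StructureModel(1, atoms)
    regions = [
        RegionDefinition.catalytic_zone(chain_id),
        RegionDefinition(
            "mt_loop", [ResidueKey(chain_id, seq, name) for seq, name in MT_LOOP_RESIDUES]
        ),
    ]
    return receptor, regions


# --- pose ensembles ----------------------------------------------------------

def gen_pose_ensemble(
    peptide_template: StructureModel,
    anchors: Sequence[tuple[np.ndarray, float, float]],
    rng: int | np.random.Generator,
    n_poses: int = 100,
    label: str = "poses",
    mass_mode: str = "element",
) -> tuple[Ensemble, np.ndarray]:
    """Docked-pose stand-in: rigid placements with mixture-distributed COMs.

    ``anchors`` is a list of ``(anchor_point, weight, spread)``; each pose
    picks an anchor by weight, draws its center of mass from an isotropic
    Gaussian of SD ``spread`` around the anchor, and takes a uniformly
    random orientation.  Returns the ensemble and the anchor index of each
    pose (the ground-truth mixture component).
    """
    rng = _rng(rng)
    weights = np.array([w for _, w, _ in anchors], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("anchor weights must sum to 1")
    template_com = center_of_mass(peptide_template, mass_mode)
    components = rng.choice(len(anchors), size=n_poses, p=weights)
    models = []
    for i, comp in enumerate(components):
        anchor, _, spread = anchors[comp]
        target_com = np.asarray(anchor, float) + rng.normal(scale=spread, size=3)
        R = Rotation.random(rng=rng).as_matrix()
        coords = (peptide_template.coords - template_com) @ R.T + target_com
        models.append(peptide_template.with_coords(coords, model_id=i + 1))
    return Ensemble(models, label=label), components


def region_anchor(receptor: StructureModel, region: RegionDefinition) -> np.ndarray:
    """Centroid of a region's heavy atoms — a natural pose anchor."""
    return region.atom_coords(receptor).mean(axis=0)


# --- contact-count profiles --------------------------------------------------

def gen_contact_profile(
    label: str,
    residues: Sequence[ResidueKey],
    means: Sequence[float],
    sds: Sequence[float] | float,
    rng: int | np.random.Generator,
    n_poses: int = 100,
    model: str = "normal",
) -> ContactProfile:
    """Contact-count matrix with per-residue planted means and SDs.

    ``model="normal"`` draws normal(mean, sd) counts rounded to integers
    and truncated at zero (the summary statistics the screen consumes);
    ``model="poisson"`` draws Poisson(mean) counts.
    """
    rng = _rng(rng)
    means = np.asarray(means, dtype=float)
    if (means < 0).any():
        raise ValueError("per-residue mean contact counts must be >= 0")
    if len(means) != len(residues):
        raise ValueError("need one mean per zone residue")
    if model == "normal":
        sds = np.broadcast_to(np.asarray(sds, dtype=float), means.shape)
        counts = rng.normal(loc=means, scale=sds, size=(n_poses, len(means)))
        counts = np.clip(np.rint(counts), 0, None).astype(int)
    elif model == "poisson":
        counts = rng.poisson(lam=means, size=(n_poses, len(means)))
    else:
        raise ValueError("count model must be 'normal' or 'poisson'")
    return ContactProfile(label, list(residues), counts)


def write_synthetic_bundle(
    outdir,
    seed: int,
    n_conformer_models: int = 40,
    n_poses: int = 100,
    inactive_deficits: Mapping[str, set[int]] | None = None,
    conformers_per_inactive: Mapping[str, int] | None = None,
    delta: float = 2.0,
    base_mean: float = 3.0,
    sd: float = 1.0,
):
    """Write a complete pipeline input bundle to ``outdir``.

    The bundle contains, for the five studied peptides: a receptor PDB with
    region definitions (YAML), a conformer ensemble PDB per ligand (three
    planted conformations, 6 A apart, 0.5 A jitter), a 100-pose ensemble
    PDB per ligand (catalytic-zone-anchored for the linear peptides,
    MT-Loop-anchored for the cyclic query), and planted contact-profile
    TSVs for the statistical stage, plus a ready-to-run ``bundle.yaml``.
    Returns ``(bundle_yaml_path, ground_truth_dict)``.
    """
    import yaml as _yaml
    from pathlib import Path as _Path

    from .pose_regions import save_regions
    from .structure_io import write_multimodel_pdb

    outdir = _Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    receptor, regions = gen_receptor()
    write_multimodel_pdb(outdir / "receptor.pdb", Ensemble([receptor], label="receptor"))
    save_regions(outdir / "regions.yaml", regions)

    cat_anchor = region_anchor(receptor, regions[0])
    mt_anchor = region_anchor(receptor, regions[1])
    pose_mixtures = {
        "lumcorin": [(cat_anchor, 0.7, 2.0), (mt_anchor, 0.2, 2.0), (FAR_POINT, 0.1, 2.0)],
        "L9M": [(cat_anchor, 0.7, 2.0), (mt_anchor, 0.2, 2.0), (FAR_POINT, 0.1, 2.0)],
        "D9M": [(cat_anchor, 0.6, 2.0), (mt_anchor, 0.3, 2.0), (FAR_POINT, 0.1, 2.0)],
        "F9M": [(cat_anchor, 0.8, 2.0), (mt_anchor, 0.1, 2.0), (FAR_POINT, 0.1, 2.0)],
        "L9Mc": [(mt_anchor, 0.6, 2.0), (cat_anchor, 0.3, 2.0), (FAR_POINT, 0.1, 2.0)],
    }

    zone_residues = [ResidueKey("A", seq, name) for seq, name in CATALYTIC_ZONE_RESIDUES]
    if inactive_deficits is None:
        inactive_deficits = {"D9M": {5, 6, 7}, "F9M": {1, 2, 12, 13}}
    conformers_per_inactive = conformers_per_inactive or {"D9M": 5, "F9M": 2}
    actives, inactives, planted = make_training_panel(
        rng, zone_residues,
        active_labels=("lumcorin", "L9M"),
        inactive_deficits=inactive_deficits,
        conformers_per_inactive=conformers_per_inactive,
        base_mean=base_mean, sd=sd, delta=delta, n_poses=n_poses,
    )
    # the query engages the zone like an active except at two planted residues
    query_means = np.full(len(zone_residues), base_mean)
    query_means[[2, 7]] = base_mean + delta  # positions of 198F and 203Y
    query_profiles = [
        gen_contact_profile("L9Mc", zone_residues, query_means, sd, rng, n_poses)
    ]

    truth = {"planted_key_residues": sorted(r.short for r in planted),
             "pose_truth": {}, "conformer_truth": {}}
    ligand_cfg = {}
    for label, activity in PEPTIDE_ACTIVITY.items():
        template = peptide_ca_template(label)
        templates = make_conformer_templates(template, 3, separation=6.0, rng=rng)
        conf_ens, conf_labels = gen_conformer_ensemble(
            templates, (0.5, 0.3, 0.2), n_conformer_models, jitter_sd=0.5,
            rng=rng, label=label,
        )
        write_multimodel_pdb(outdir / f"conformers_{label}.pdb", conf_ens)
        truth["conformer_truth"][label] = conf_labels.tolist()
        pose_ens, components = gen_pose_ensemble(
            template, pose_mixtures[label], rng, n_poses=n_poses, label=label
        )
        write_multimodel_pdb(outdir / f"poses_{label}.pdb", pose_ens)
        truth["pose_truth"][label] = components.tolist()
        if activity == "active":
            profiles = actives[label]
        elif activity == "inactive":
            profiles = inactives[label]
        else:
            profiles = query_profiles
        profile_paths = []
        for i, prof in enumerate(profiles):
            p = f"profile_{label}_{i}.tsv"
            prof.to_tsv(outdir / p)
            profile_paths.append(p)
        ligand_cfg[label] = {
            "class": activity,
            "conformers": f"conformers_{label}.pdb",
            "poses": [f"poses_{label}.pdb"],
            "profiles": profile_paths,
        }

    bundle = {
        "receptor": "receptor.pdb",
        "regions": "regions.yaml",
        "zone": "catalytic",
        "seed": seed,
        "ligands": ligand_cfg,
    }
    bundle_path = outdir / "bundle.yaml"
    bundle_path.write_text(_yaml.safe_dump(bundle, sort_keys=False))
    return bundle_path, truth


def make_training_panel(
    rng: int | np.random.Generator,
    residues: Sequence[ResidueKey] | None = None,
    active_labels: Sequence[str] = ("lumcorin", "L9M"),
    inactive_deficits: Mapping[str, set[int]] | None = None,
    conformers_per_inactive: Mapping[str, int] | None = None,
    base_mean: float = 3.0,
    sd: float = 1.0,
    delta: float = 2.0,
    n_poses: int = 100,
) -> tuple[dict[str, list[ContactProfile]], dict[str, list[ContactProfile]], set[ResidueKey]]:
    """Training panel with planted discriminative residues.

    Active peptides engage every zone residue at ``base_mean`` contacts;
    each inactive peptide's mean is lowered by ``delta`` at the residue
    *positions* (indices into the zone) listed in ``inactive_deficits``,
    so those residues are exactly the ones an ideal screen should flag for
    that inactive.  Returns (actives, inactives, planted key set = union
    of the deficit sets).
    """
    rng = _rng(rng)
    if residues is None:
        residues = [ResidueKey("A", seq, name) for seq, name in CATALYTIC_ZONE_RESIDUES]
    if inactive_deficits is None:
        inactive_deficits = {"D9M": {5, 6, 7}, "F9M": {1, 2, 12, 13}}
    conformers_per_inactive = conformers_per_inactive or {}
    actives = {
        lab: [gen_contact_profile(lab, residues, [base_mean] * len(residues), sd, rng, n_poses)]
        for lab in active_labels
    }
    inactives: dict[str, list[ContactProfile]] = {}
    for lab, deficit in inactive_deficits.items():
        means = np.full(len(residues), base_mean)
        means[list(deficit)] = max(base_mean - delta, 0.0)
        n_conf = conformers_per_inactive.get(lab, 1)
        inactives[lab] = [
            gen_contact_profile(lab, residues, means, sd, rng, n_poses)
            for _ in range(n_conf)
        ]
    planted = {residues[i] for d in inactive_deficits.values() for i in d}
    return actives, inactives, planted
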