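"""Per-residue receptor-ligand contact counting over pose ensembles.

A contact is an (receptor atom, ligand atom) pair at a distance strictly
below the cutoff (default 4.0 A).  For a zone of interest — typically the
15 residues of the MMP-14 catalytic site — each docked pose contributes a
vector of per-residue pair counts; over the pose ensemble (canonically the
100 best docking solutions) the per-residue sample mean and standard
deviation summarize how intensely each receptor residue is engaged by the
peptide.  These count distributions are the raw material for the
statistical screen in :mod:`pepsurf.discrim_stats`.

Counting is pair-level: one ligand atom within the cutoff of two atoms of
the same receptor residue contributes two contacts, matching the use of
contact *numbers* (not binary indicators) in the downstream comparisons.
A binary per-residue mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pose_regions import RegionDefinition, ResidueKey
from .structure_io import Ensemble, StructureModel


@dataclass
class ContactConfig:
    cutoff: float = 4.0          # A; strict "<" comparison
    heavy_atoms_only: bool = True
    binary: bool = False         # per-residue indicator instead of pair counts

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass
class ContactProfile:
    """Contact-count matrix of one ligand ensemble against a receptor zone.

    ``counts`` has one row per pose and one column per zone residue, in the
    zone definition's residue order.
    """

    ligand_label: str
    residues: list[ResidueKey]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.residues):
            raise ValueError("counts must be (n_poses, n_zone_residues)")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")

    @property
    def n_poses(self) -> int:
        return self.counts.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.n_poses < 2:
            return np.zeros(self.counts.shape[1])
        return self.counts.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: ligand, pose, residue, count."""
        n_poses, n_res = self.counts.shape
        return pd.DataFrame(
            {
                "ligand": self.ligand_label,
                "pose": np.repeat(np.arange(n_poses), n_res),
                "residue": [str(r) for r in self.residues] * n_poses,
                "count": self.counts.reshape(-1),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, ligand_label: str | None = None) -> "ContactProfile":
        df = pd.read_csv(path, sep="\t")
        label = ligand_label or str(df["ligand"].iloc[0])
        residues = [ResidueKey.parse(r) for r in df[df["pose"] == df["pose"].iloc[0]]["residue"]]
        n_res = len(residues)
        counts = df["count"].to_numpy().reshape(-1, n_res)
        return cls(label, residues, counts)


def _zone_atom_table(
    receptor: StructureModel, zone: RegionDefinition, heavy_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of zone atoms and the zone-residue index of each."""
    index = {
        (r.chain_id, r.residue_seq, r.residue_name): i for i, r in enumerate(zone.residues)
    }
    coords, owners = [], []
    seen = set()
    for a in receptor.atoms:
        key = (a.chain_id, a.residue_seq, a.residue_name)
        if key in index and not (heavy_only and a.is_hydrogen):
            coords.append(a.coords)
            owners.append(index[key])
            seen.add(key)
    missing = [r for r in zone.residues if (r.chain_id, r.residue_seq, r.residue_name) not in seen]
    if missing:
        raise ValueError(
            f"zone residues missing from receptor: {', '.join(str(r) for r in missing)}"
        )
    return np.array(coords), np.array(owners)


def count_contacts(
    receptor: StructureModel,
    pose: StructureModel,
    zone: RegionDefinition,
    config: ContactConfig | None = None,
) -> np.ndarray:
    """Per-zone-residue contact counts between receptor and one pose.

    Uses a k-d tree over ligand atoms; a pair counts iff its distance is
    strictly below ``config.cutoff``.
    """
    config = config or ContactConfig()
    zone_coords, owners = _zone_atom_table(receptor, zone, config.heavy_atoms_only)
    lig = pose.select(heavy_only=True) if config.heavy_atoms_only else pose
    lig_coords = lig.coords
    tree = cKDTree(lig_coords)
    counts = np.zeros(len(zone.residues), dtype=int)
    neighbor_lists = tree.query_ball_point(zone_coords, r=config.cutoff)
    for zi, neighbors in enumerate(neighbor_lists):
        if not neighbors:
            continue
        d = np.linalg.norm(lig_coords[neighbors] - zone_coords[zi], axis=1)
        n_strict = int((d < config.cutoff).sum())
        if config.binary:
            counts[owners[zi]] = min(1, counts[owners[zi]] + (n_strict > 0))
        else:
            counts[owners[zi]] += n_strict
    return counts


def profile_ensemble(
    receptor: StructureModel,
    poses: Ensemble,
    zone: RegionDefinition,
    config: ContactConfig | None = None,
    label: str | None = None,
) -> ContactProfile:
    """Stack per-pose contact counts into a :class:`ContactProfile`."""
    config = config or ContactConfig()
    counts = np.array([count_contacts(receptor, p, zone, config) for p in poses])
    return ContactProfile(label or poses.label, list(zone.residues), counts)
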