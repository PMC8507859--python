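"""Localization of docked poses on the receptor surface.

Each docking solution is reduced to the center of mass of the peptide; the
resulting point cloud is partitioned with PAM (k-medoids, deterministic
BUILD + SWAP), and each cluster is attributed to a named receptor region
— the catalytic zone around the active site, the MT-Loop insertion, or
"other" — by the distance from the cluster's medoid to the nearest heavy
atom of each region.  Region occupancy is the fraction of poses whose
cluster lands on that region, the quantity used to decide whether a
peptide preferentially targets the catalytic site or an exosite.

The PAM implementation below is the classical BUILD/SWAP scheme, extended
with a bounded multi-swap escape phase, and is fully deterministic (ties
resolved by lowest index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .structure_io import Ensemble, StructureModel, center_of_mass

OTHER_REGION = "other"

#: The 15 residues lining the MMP-14 active site, used as the built-in
#: contact-profiling zone (chain A, PDB numbering of the catalytic domain).
CATALYTIC_ZONE_RESIDUES: tuple[tuple[int, str], ...] = (
    (196, "GLY"), (197, "GLY"), (198, "PHE"), (199, "LEU"), (200, "ALA"),
    (201, "HIS"), (202, "ALA"), (203, "TYR"), (236, "VAL"), (239, "HIS"),
    (240, "GLU"), (243, "HIS"), (259, "PRO"), (260, "PHE"), (261, "TYR"),
)


@dataclass(frozen=True)
class ResidueKey:
    chain_id: str
    residue_seq: int
    residue_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_seq}:{self.residue_name}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        chain, seq, name = text.split(":")
        return cls(chain, int(seq), name)

    @property
    def short(self) -> str:
        """Compact residue tag, e.g. ``201H`` for His201."""
        return f"{self.residue_seq}{_ONE_LETTER.get(self.residue_name, 'X')}"


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class RegionDefinition:
    """A named set of receptor residues (e.g. catalytic zone, MT-Loop)."""

    region_name: str
    residues: list[ResidueKey]

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"region {self.region_name!r} has no residues")

    def validate_against(self, receptor: StructureModel) -> None:
        """Raise if any region residue is absent from the receptor."""
        present = {(a.chain_id, a.residue_seq, a.residue_name) for a in receptor.atoms}
        for r in self.residues:
            if (r.chain_id, r.residue_seq, r.residue_name) not in present:
                raise ValueError(
                    f"region {self.region_name!r}: residue {r} not found in receptor"
                )

    def atom_coords(self, receptor: StructureModel, heavy_only: bool = True) -> np.ndarray:
        keys = {(r.chain_id, r.residue_seq, r.residue_name) for r in self.residues}
        coords = [
            a.coords
            for a in receptor.atoms
            if (a.chain_id, a.residue_seq, a.residue_name) in keys
            and not (heavy_only and a.is_hydrogen)
        ]
        if not coords:
            raise ValueError(f"region {self.region_name!r} matches no receptor atoms")
        return np.array(coords)

    @classmethod
    def catalytic_zone(cls, chain_id: str = "A") -> "RegionDefinition":
        return cls(
            "catalytic",
            [ResidueKey(chain_id, seq, name) for seq, name in CATALYTIC_ZONE_RESIDUES],
        )


def load_regions(path: str | Path) -> list[RegionDefinition]:
    """Read region definitions from YAML/JSON: name -> ["A:196:GLY", ...]."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("region file must map region names to residue selector lists")
    return [
        RegionDefinition(name, [ResidueKey.parse(s) for s in selectors])
        for name, selectors in data.items()
    ]


def save_regions(path: str | Path, regions: list[RegionDefinition]) -> None:
    data = {r.region_name: [str(k) for k in r.residues] for r in regions}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class PoseLocalization:
    pose_coms: np.ndarray                 # (n_poses, 3)
    pam_medoids: list[int]                # pose indices
    pam_labels: np.ndarray                # (n_poses,) cluster ids
    silhouette: float | None = None
    region_assignment: dict[int, str] = field(default_factory=dict)   # cluster -> region
    occupancy: dict[str, float] = field(default_factory=dict)         # region -> fraction

    @property
    def pose_regions(self) -> list[str]:
        """Region of each pose, inherited from its cluster."""
        return [self.region_assignment[int(l)] for l in self.pam_labels]


# --- PAM / k-medoids ---------------------------------------------------------

def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        # gain of adding candidate j: sum over points of max(0, d_near - d(i,j))
        gains = np.maximum(d_near[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _swap_descent(dist: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest single-swap descent (classical PAM SWAP phase)."""
    n = dist.shape[0]
    medoids = list(medoids)
    current = float(dist[:, medoids].min(axis=1).sum())
    while True:
        best = (current - 1e-12, None, None)
        for mi in range(len(medoids)):
            others = [m for j, m in enumerate(medoids) if j != mi]
            d_others = (
                dist[:, others].min(axis=1) if others else np.full(n, np.inf)
            )
            # cost of swapping medoid mi for every candidate h at once
            costs = np.minimum(d_others[:, None], dist).sum(axis=0)
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            if costs[h] < best[0]:
                best = (float(costs[h]), mi, h)
        if best[1] is None:
            return medoids, current
        medoids[best[1]] = best[2]
        current = best[0]


def _multi_swap_escape(
    dist: np.ndarray, medoids: list[int], current: float
) -> tuple[list[int], float, bool]:
    """Try replacing 2 (and, on small inputs, 3) medoids simultaneously.

    Single-swap descent can stall in local optima where several medoids
    must move together; this deeper neighborhood removes them at modest
    cost.  Returns the improved configuration and whether one was found.
    """
    import itertools

    n = dist.shape[0]
    k = len(medoids)
    non = np.array([h for h in range(n) if h not in medoids])
    best = (current - 1e-12, None)
    if k >= 2 and k * (k - 1) / 2 * len(non) <= 50_000:
        for mi, mj in itertools.combinations(range(k), 2):
            keep = [m for x, m in enumerate(medoids) if x not in (mi, mj)]
            d_keep = dist[:, keep].min(axis=1) if keep else np.full(n, np.inf)
            for h1 in non:
                d1 = np.minimum(d_keep, dist[:, h1])
                costs = np.minimum(d1[:, None], dist[:, non]).sum(axis=0)
                h2 = int(np.argmin(costs))
                if costs[h2] < best[0]:
                    best = (float(costs[h2]), keep + [int(h1), int(non[h2])])
    if best[1] is None and k >= 3 and len(non) ** 2 * k <= 20_000:
        for trio in itertools.combinations(range(k), 3):
            keep = [m for x, m in enumerate(medoids) if x not in trio]
            d_keep = dist[:, keep].min(axis=1) if keep else np.full(n, np.inf)
            for h1, h2 in itertools.combinations(non, 2):
                d12 = np.minimum(d_keep, np.minimum(dist[:, h1], dist[:, h2]))
                costs = np.minimum(d12[:, None], dist[:, non]).sum(axis=0)
                h3 = int(np.argmin(costs))
                if costs[h3] < best[0]:
                    best = (float(costs[h3]), keep + [int(h1), int(h2), int(non[h3])])
    if best[1] is None:
        return medoids, current, False
    return best[1], best[0], True


def pam_cluster(points: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """PAM k-medoids on Euclidean distances.

    Deterministic BUILD initialization followed by steepest-descent SWAP
    until no single swap lowers the total point-to-medoid cost, then a
    bounded multi-swap escape phase (re-entering SWAP descent after each
    escape) to step over the local optima single swaps cannot leave.
    Fully deterministic; ties resolve to the lowest index.  Returns
    ``(medoid indices, labels, cost)``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    dist = cdist(pts, pts)
    medoids, current = _swap_descent(dist, _pam_build(dist, k))
    while True:
        medoids, current, escaped = _multi_swap_escape(dist, medoids, current)
        if not escaped:
            break
        medoids, current = _swap_descent(dist, medoids)
    medoids = sorted(medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return medoids, labels, float(dist[:, medoids].min(axis=1).sum())


def choose_k(
    points: np.ndarray,
    k_range: tuple[int, int] = (2, 8),
    return_scores: bool = False,
):
    """Pick the number of pose clusters by mean silhouette (ties -> smallest k)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("silhouette selection needs at least 3 points")
    k_lo, k_hi = max(2, k_range[0]), min(n - 1, k_range[1])
    if k_lo > k_hi:
        raise ValueError(f"k range [{k_range[0]}, {k_range[1]}] infeasible for n={n}")
    scores: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        _, labels, _ = pam_cluster(pts, k)
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(pts, labels))
    best_k = max(scores, key=lambda k: (scores[k], -k))
    return (best_k, scores) if return_scores else best_k


# --- region assignment -------------------------------------------------------

def assign_regions(
    localization: PoseLocalization,
    receptor: StructureModel,
    regions: list[RegionDefinition],
    max_dist: float = 15.0,
    per_pose: bool = False,
) -> PoseLocalization:
    """Attribute each pose cluster to a receptor region and compute occupancy.

    A cluster is assigned to the region whose heavy atoms come closest to
    the cluster medoid's center of mass; clusters farther than ``max_dist``
    from every region fall into ``"other"``.  With ``per_pose=True`` each
    pose COM is assigned individually instead (sensitivity mode; cluster
    assignment then records the majority region of each cluster).
    """
    for region in regions:
        region.validate_against(receptor)
    region_coords = {r.region_name: r.atom_coords(receptor) for r in regions}

    def nearest_region(point: np.ndarray) -> str:
        best_name, best_d = OTHER_REGION, np.inf
        for name, coords in region_coords.items():
            d = float(np.min(np.linalg.norm(coords - point, axis=1)))
            if d < best_d:
                best_name, best_d = name, d
        return best_name if best_d <= max_dist else OTHER_REGION

    labels = localization.pam_labels
    n_poses = len(labels)
    if per_pose:
        pose_regions = [nearest_region(c) for c in localization.pose_coms]
        assignment = {}
        for ci in range(len(localization.pam_medoids)):
            members = [pose_regions[i] for i in np.flatnonzero(labels == ci)]
            assignment[ci] = max(sorted(set(members)), key=members.count)
    else:
        assignment = {
            ci: nearest_region(localization.pose_coms[m])
            for ci, m in enumerate(localization.pam_medoids)
        }
        pose_regions = [assignment[int(l)] for l in labels]

    occupancy = {name: 0.0 for name in list(region_coords) + [OTHER_REGION]}
    for r in pose_regions:
        occupancy[r] += 1.0 / n_poses
    localization.region_assignment = assignment
    localization.occupancy = occupancy
    return localization


def localize_poses(
    poses: Ensemble,
    receptor: StructureModel,
    regions: list[RegionDefinition],
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    max_dist: float = 15.0,
    mass_mode: str = "element",
) -> PoseLocalization:
    """Full pose-localization stage: COMs -> PAM -> region occupancies."""
    coms = np.array([center_of_mass(m, mass_mode) for m in poses])
    if k is None:
        k = choose_k(coms, k_range)
    medoids, labels, _ = pam_cluster(coms, k)
    sil = None
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(coms, labels))
    loc = PoseLocalization(coms, medoids, labels, silhouette=sil)
    return assign_regions(loc, receptor, regions, max_dist=max_dist)
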