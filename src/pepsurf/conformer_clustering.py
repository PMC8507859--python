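"""Conformer selection by gromos RMSD clustering with an adaptive cutoff.

A molecular-dynamics trajectory of a short peptide samples a handful of
recurring conformations.  Before rigid-body docking, the ensemble is
reduced to a few representative structures: models are clustered on
pairwise post-fit RMSD with the gromos neighbor-counting algorithm
(Daura's scheme: the model with the most neighbors within the cutoff
seeds a cluster, the cluster is removed, repeat), and only clusters whose
population exceeds a retention threshold contribute their center as a
docking representative.

The cutoff is adaptive: the scan walks the 2.2-2.8 A range and keeps the
smallest cutoff at which the retained clusters jointly cover at least 80%
of the ensemble, so that a small number of well-populated conformational
classes emerges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Ensemble, rmsd_after_fit

DEFAULT_FIT_SELECTION = ("CA",)


@dataclass
class ClusteringConfig:
    cutoff_min: float = 2.2        # A
    cutoff_max: float = 2.8        # A
    cutoff_step: float = 0.1       # A
    fit_selection: tuple[str, ...] = DEFAULT_FIT_SELECTION
    retention_threshold: float = 0.10  # fraction of the ensemble
    coverage_target: float = 0.80      # retained clusters must cover this much

    def __post_init__(self):
        if not (0 < self.cutoff_min <= self.cutoff_max):
            raise ValueError("require 0 < cutoff_min <= cutoff_max")
        if self.cutoff_step <= 0:
            raise ValueError("cutoff_step must be positive")
        if not (0 < self.retention_threshold < 1):
            raise ValueError("retention_threshold must be in (0, 1)")

    def cutoffs(self) -> np.ndarray:
        n = int(round((self.cutoff_max - self.cutoff_min) / self.cutoff_step))
        return self.cutoff_min + self.cutoff_step * np.arange(n + 1)


@dataclass
class Cluster:
    center: int                 # model index of the cluster center
    members: list[int]          # model indices, center included
    fraction: float             # population fraction of the ensemble

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    cutoff_used: float
    clusters: list[Cluster]     # ordered by decreasing size, ties by center index
    retained: list[Cluster] = field(default_factory=list)
    coverage_warning: bool = False

    @property
    def labels(self) -> np.ndarray:
        """Per-model cluster index (into ``clusters``)."""
        n = sum(len(c) for c in self.clusters)
        lab = np.empty(n, dtype=int)
        for ci, c in enumerate(self.clusters):
            lab[c.members] = ci
        return lab

    @property
    def representative_indices(self) -> list[int]:
        """Centers of the retained clusters — the docking representatives."""
        return [c.center for c in self.retained]


def pairwise_rmsd_matrix(
    ensemble: Ensemble, selection: tuple[str, ...] | None = DEFAULT_FIT_SELECTION
) -> np.ndarray:
    """Symmetric matrix of post-fit RMSDs between all model pairs."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("pairwise RMSD needs an ensemble of size >= 2")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = rmsd_after_fit(ensemble[i], ensemble[j], selection)
            mat[i, j] = mat[j, i] = r
    return mat


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if (m < 0).any() or not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric and non-negative")
    return m


def gromos_cluster(
    matrix: np.ndarray,
    cutoff: float,
    retention_threshold: float | None = None,
) -> ClusterResult:
    """Gromos (neighbor-counting) clustering of an RMSD matrix.

    At each step the remaining model with the most remaining neighbors at
    RMSD <= ``cutoff`` becomes a cluster center (ties broken by lowest
    model index); it and its neighbors form a cluster and are removed.
    Every model ends in exactly one cluster and each center is a member of
    its own cluster.
    """
    m = _check_matrix(matrix)
    n = m.shape[0]
    within = m <= cutoff
    np.fill_diagonal(within, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (within & remaining).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[center] & remaining)
        clusters.append(Cluster(center, members.tolist(), len(members) / n))
        remaining[members] = False
    clusters.sort(key=lambda c: (-len(c.members), c.center))
    result = ClusterResult(cutoff_used=float(cutoff), clusters=clusters)
    if retention_threshold is not None:
        result.retained = [c for c in clusters if c.fraction >= retention_threshold]
    return result


def adaptive_cutoff_scan(matrix: np.ndarray, config: ClusteringConfig | None = None) -> ClusterResult:
    """Scan cutoffs and keep the smallest one with sufficient retained coverage.

    Runs :func:`gromos_cluster` at each cutoff of the configured range and
    returns the result at the smallest cutoff for which clusters at or
    above the retention threshold jointly cover ``coverage_target`` of the
    ensemble.  If no cutoff qualifies, the result at ``cutoff_max`` is
    returned with ``coverage_warning`` set.
    """
    config = config or ClusteringConfig()
    last = None
    for cutoff in config.cutoffs():
        res = gromos_cluster(matrix, float(cutoff), config.retention_threshold)
        coverage = sum(c.fraction for c in res.retained)
        if coverage >= config.coverage_target:
            return res
        last = res
    assert last is not None
    last.coverage_warning = True
    return last


def cluster_ensemble(ensemble: Ensemble, config: ClusteringConfig | None = None) -> ClusterResult:
    """Convenience: pairwise RMSD matrix + adaptive scan in one call."""
    config = config or ClusteringConfig()
    matrix = pairwise_rmsd_matrix(ensemble, config.fit_selection)
    return adaptive_cutoff_scan(matrix, config)
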