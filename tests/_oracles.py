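"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (brute force, exhaustive enumeration,
generic optimization) and shares no code path with the implementations it
validates.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def naive_gromos(matrix: np.ndarray, cutoff: float) -> list[tuple[int, list[int]]]:
    """Neighbor-counting clustering, recomputed from scratch each round.

    Returns (center, members) pairs in order of extraction.
    """
    n = matrix.shape[0]
    remaining = list(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, None
        for i in remaining:
            members = [j for j in remaining if matrix[i, j] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append((best_center, sorted(best_members)))
        remaining = [j for j in remaining if j not in set(best_members)]
    return clusters


def brute_contact_counts(
    receptor_coords_by_residue: list[np.ndarray],
    ligand_coords: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """All-pairs O(N*M) contact counting, strict '<' cutoff."""
    counts = np.zeros(len(receptor_coords_by_residue), dtype=int)
    for ri, res_coords in enumerate(receptor_coords_by_residue):
        for a in res_coords:
            for b in ligand_coords:
                if np.linalg.norm(a - b) < cutoff:
                    counts[ri] += 1
    return counts


def pam_exhaustive(points: np.ndarray, k: int) -> tuple[float, list[tuple[int, ...]]]:
    """Global k-medoids optimum by enumerating all medoid subsets.

    Returns (minimal cost, list of all optimal medoid subsets).
    """
    pts = np.asarray(points, float)
    n = len(pts)
    dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    best_cost, best_sets = np.inf, []
    for subset in itertools.combinations(range(n), k):
        cost = dist[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_sets = cost, [subset]
        elif abs(cost - best_cost) <= 1e-12:
            best_sets.append(subset)
    return float(best_cost), best_sets


def min_rmsd_by_optimization(a: np.ndarray, b: np.ndarray, n_starts: int = 24) -> float:
    """Global minimum post-fit RMSD via multi-start rotation optimization.

    Parameterizes the rotation as a rotation vector and minimizes the RMSD
    of b (centered, rotated) against a (centered) from many seeded starts.
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((bc @ R.T - ac) ** 2, axis=1))))

    rng = np.random.default_rng(7)
    best = np.inf
    starts = [np.zeros(3)] + [
        Rotation.random(rng=rng).as_rotvec() for _ in range(n_starts - 1)
    ]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


def pooled_t_reference(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Reference two-sample pooled t via scipy's canned routine."""
    from scipy import stats

    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
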