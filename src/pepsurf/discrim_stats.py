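"""Discriminative-residue statistics and activity prediction.

The training logic mirrors how a small panel of peptides with known
activity against MMP-14 is used to calibrate the screen: contact profiles
of active (inhibitory) and inactive peptides are compared residue by
residue with a two-sample pooled-variance Student's t-test at alpha = 0.05.
A receptor residue is *highlighted* against one inactive peptide when every
active peptide makes significantly more contacts with it than that inactive
does (aggregated over conformer-level comparisons when a ligand contributed
several representative conformations).  The union of the per-inactive
highlighted sets forms the *key residues* — the residues whose engagement
discriminates inhibitors from non-inhibitors.

Prediction then asks, for a query peptide of unknown activity, at how many
key residues its contact pattern differs significantly (two-sided, no
direction requirement) from each known active.  If fewer than half of the
key residues differ versus every active, the query is called
inhibitor-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .contact_profiling import ContactProfile
from .pose_regions import ResidueKey


@dataclass
class StatsConfig:
    alpha: float = 0.05
    welch: bool = False                      # pooled-variance Student's t by default
    direction_filter: bool = True            # training: require mean(active) > mean(inactive)
    conformer_aggregation_fraction: float = 0.5
    prediction_max_fraction: float = 0.5
    multiple_testing: str = "none"           # "none" or "bh"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for f in (self.conformer_aggregation_fraction, self.prediction_max_fraction):
            if not (0 < f <= 1):
                raise ValueError("fractions must be in (0, 1]")
        if self.multiple_testing not in ("none", "bh"):
            raise ValueError("multiple_testing must be 'none' or 'bh'")


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def students_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Two-sample pooled-variance Student's t-test (two-sided).

    df = n_a + n_b - 2.  Degenerate zero-variance inputs are resolved
    deterministically: equal means give (t=0, p=1); unequal means with zero
    pooled variance give p=0 with the ``degenerate`` flag set.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = a.mean() - b.mean()
    pooled = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if pooled == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0)
        return TTestResult(np.sign(diff) * np.inf, 0.0, degenerate=True)
    se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    t = float(diff / se)
    p = float(2.0 * stats.t.sf(abs(t), df=n_a + n_b - 2))
    return TTestResult(t, p)


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t-test (optional alternative)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            return TTestResult(0.0, 1.0)
        return TTestResult(np.sign(diff) * np.inf, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p))


@dataclass
class ComparisonResult:
    """Per-residue comparison of two contact profiles (A vs B)."""

    label_a: str
    label_b: str
    residues: list[ResidueKey]
    t: np.ndarray
    p: np.ndarray
    mean_diff: np.ndarray            # mean(A) - mean(B)
    significant_higher: np.ndarray   # bool; p < alpha and (if filtered) diff > 0
    alpha: float

    @property
    def flagged(self) -> set[ResidueKey]:
        return {r for r, f in zip(self.residues, self.significant_higher) if f}


def compare_profiles(
    profile_a: ContactProfile,
    profile_b: ContactProfile,
    config: StatsConfig | None = None,
) -> ComparisonResult:
    """Residue-wise t-test between the pose-level count columns of two profiles."""
    config = config or StatsConfig()
    if profile_a.residues != profile_b.residues:
        raise ValueError(
            f"zone mismatch between profiles {profile_a.ligand_label!r} "
            f"and {profile_b.ligand_label!r}"
        )
    test = welch_t if config.welch else students_t
    n_res = len(profile_a.residues)
    t = np.empty(n_res)
    p = np.empty(n_res)
    for i in range(n_res):
        res = test(profile_a.counts[:, i], profile_b.counts[:, i])
        t[i], p[i] = res.t, res.p
    if config.multiple_testing == "bh":
        p = stats.false_discovery_control(p, method="bh")
    mean_diff = profile_a.mean - profile_b.mean
    sig = p < config.alpha
    if config.direction_filter:
        sig = sig & (mean_diff > 0)
    return ComparisonResult(
        profile_a.ligand_label, profile_b.ligand_label,
        list(profile_a.residues), t, p, mean_diff, sig, config.alpha,
    )


@dataclass
class KeyResidueSet:
    """Discriminative receptor residues with their per-inactive provenance."""

    residues: frozenset[ResidueKey]
    provenance: dict[str, frozenset[ResidueKey]] = field(default_factory=dict)

    def __post_init__(self):
        if self.provenance:
            union = frozenset().union(*self.provenance.values())
            if union != self.residues:
                raise ValueError("key set must equal the union of per-inactive subsets")

    def __len__(self) -> int:
        return len(self.residues)

    def short_names(self) -> list[str]:
        return sorted((r.short for r in self.residues), key=lambda s: int(s[:-1]))

    @classmethod
    def from_highlights(cls, highlighted: Mapping[str, set[ResidueKey]]) -> "KeyResidueSet":
        """Apply the union rule to per-inactive highlighted residue sets."""
        prov = {k: frozenset(v) for k, v in highlighted.items()}
        return cls(frozenset().union(*prov.values()) if prov else frozenset(), prov)


def derive_key_residues(
    actives: Mapping[str, Sequence[ContactProfile]],
    inactives: Mapping[str, Sequence[ContactProfile]],
    config: StatsConfig | None = None,
) -> KeyResidueSet:
    """Derive the key-residue set from an active/inactive training panel.

    ``actives`` and ``inactives`` map ligand labels to one profile per
    retained conformer.  For an (active, inactive) ligand pair, a residue
    is a pair-level hit if it is flagged (significantly more contacts for
    the active) in at least ``conformer_aggregation_fraction`` of the
    conformer-by-conformer comparisons.  A residue is highlighted against
    inactive I when it is a pair-level hit for *every* active versus I;
    the key set is the union of the per-inactive highlighted sets.
    """
    config = config or StatsConfig()
    if not actives or not inactives:
        raise ValueError("training requires at least one active and one inactive ligand")
    highlighted: dict[str, set[ResidueKey]] = {}
    for inactive_label, inactive_profiles in inactives.items():
        per_active_hits: list[set[ResidueKey]] = []
        for active_label, active_profiles in actives.items():
            comparisons = [
                compare_profiles(pa, pb, config)
                for pa in active_profiles
                for pb in inactive_profiles
            ]
            residues = comparisons[0].residues
            flag_fraction = np.mean(
                [c.significant_higher for c in comparisons], axis=0
            )
            hits = {
                r
                for r, f in zip(residues, flag_fraction)
                if f >= config.conformer_aggregation_fraction
            }
            per_active_hits.append(hits)
        highlighted[inactive_label] = set.intersection(*per_active_hits)
    return KeyResidueSet.from_highlights(highlighted)


@dataclass
class ActivityCall:
    query_label: str
    differing: dict[str, frozenset[ResidueKey]]  # active label -> differing key residues
    decision: str                                # "inhibitor-like" / "not-inhibitor-like"
    rationale: str

    @property
    def is_inhibitor_like(self) -> bool:
        return self.decision == "inhibitor-like"


def predict_activity(
    query: ContactProfile | Sequence[ContactProfile],
    actives: Mapping[str, Sequence[ContactProfile]] | Mapping[str, ContactProfile],
    key_set: KeyResidueSet,
    config: StatsConfig | None = None,
) -> ActivityCall:
    """Predict whether a query peptide is inhibitor-like.

    For each active reference, the query's contact counts at the key
    residues are compared two-sided (no direction filter: any significant
    difference counts).  The query is called inhibitor-like iff versus
    every active the fraction of differing key residues is strictly below
    ``prediction_max_fraction``.  Multi-conformer inputs are aggregated
    with the same majority rule as in training.
    """
    config = config or StatsConfig()
    if not key_set.residues:
        raise ValueError("key set is empty: run derive_key_residues first")
    query_profiles = [query] if isinstance(query, ContactProfile) else list(query)
    query_label = query_profiles[0].ligand_label
    pred_config = StatsConfig(
        alpha=config.alpha, welch=config.welch, direction_filter=False,
        conformer_aggregation_fraction=config.conformer_aggregation_fraction,
        prediction_max_fraction=config.prediction_max_fraction,
        multiple_testing=config.multiple_testing,
    )
    differing: dict[str, frozenset[ResidueKey]] = {}
    for active_label, profiles in actives.items():
        active_profiles = [profiles] if isinstance(profiles, ContactProfile) else list(profiles)
        comparisons = [
            compare_profiles(pq, pa, pred_config)
            for pq in query_profiles
            for pa in active_profiles
        ]
        residues = comparisons[0].residues
        flag_fraction = np.mean([c.significant_higher for c in comparisons], axis=0)
        diff = {
            r
            for r, f in zip(residues, flag_fraction)
            if r in key_set.residues and f >= pred_config.conformer_aggregation_fraction
        }
        differing[active_label] = frozenset(diff)
    k = len(key_set)
    worst = max(len(v) for v in differing.values())
    inhibitor_like = all(len(v) / k < config.prediction_max_fraction for v in differing.values())
    decision = "inhibitor-like" if inhibitor_like else "not-inhibitor-like"
    per_active = "; ".join(
        f"vs {a}: {len(v)}/{k} key residues differ" for a, v in sorted(differing.items())
    )
    rationale = (
        f"{per_active}. Decision rule: inhibitor-like iff every fraction < "
        f"{config.prediction_max_fraction:g} (worst case {worst}/{k})."
    )
    return ActivityCall(query_label, differing, decision, rationale)
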