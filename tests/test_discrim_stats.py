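"""Student's t screening, key-residue derivation and activity prediction."""

import numpy as np
import pytest

from _oracles import pooled_t_reference

from pepsurf.contact_profiling import ContactProfile
from pepsurf.discrim_stats import (
    KeyResidueSet,
    StatsConfig,
    compare_profiles,
    derive_key_residues,
    predict_activity,
    students_t,
)
from pepsurf.pose_regions import CATALYTIC_ZONE_RESIDUES, ResidueKey
from pepsurf.synthetic_data import gen_contact_profile, make_training_panel

ZONE = [ResidueKey("A", seq, name) for seq, name in CATALYTIC_ZONE_RESIDUES]


def res(seq: int) -> ResidueKey:
    return next(r for r in ZONE if r.residue_seq == seq)


class TestStudentsT:
    def test_identical_samples(self):
        r = students_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0

    def test_p_decreases_with_shift(self, rng):
        a = rng.normal(size=30)
        ps = [students_t(a + d, a).p for d in (0.0, 0.5, 2.0, 8.0)]
        assert ps[0] == pytest.approx(1.0)
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] < 1e-12

    def test_matches_reference_implementation(self, rng):
        for _ in range(20):
            a = rng.normal(loc=rng.normal(), size=100)
            b = rng.normal(loc=rng.normal(), size=100)
            mine = students_t(a, b)
            t_ref, p_ref = pooled_t_reference(a, b)
            assert mine.t == pytest.approx(t_ref, abs=1e-10)
            assert mine.p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_degenerate_cases(self):
        equal = students_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (equal.t, equal.p, equal.degenerate) == (0.0, 1.0, False)
        unequal = students_t([2.0, 2.0], [3.0, 3.0])
        assert unequal.p == 0.0 and unequal.degenerate

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            students_t([1.0], [1.0, 2.0])


class TestCompareProfiles:
    def test_null_profiles_rarely_flagged(self, rng):
        means = [3.0] * len(ZONE)
        a = gen_contact_profile("a", ZONE, means, 1.0, rng, n_poses=100)
        b = gen_contact_profile("b", ZONE, means, 1.0, rng, n_poses=100)
        comp = compare_profiles(a, b)
        assert len(comp.flagged) <= 3  # type-I noise only at alpha=0.05

    def test_planted_shift_flagged_exactly(self, rng):
        means_b = np.full(len(ZONE), 3.0)
        means_a = means_b.copy()
        planted = [res(201), res(202), res(203)]
        for r in planted:
            means_a[ZONE.index(r)] += 2.0
        a = gen_contact_profile("a", ZONE, means_a, 1.0, rng, n_poses=100)
        b = gen_contact_profile("b", ZONE, means_b, 1.0, rng, n_poses=100)
        comp = compare_profiles(a, b)
        # the planted effect (t ~ 14) is always caught; a lone comparison may
        # add a couple of type-I flags at alpha = 0.05
        assert set(planted) <= comp.flagged
        assert len(comp.flagged - set(planted)) <= 2

    def test_antisymmetry_of_direction_filter(self, rng):
        means_b = np.full(len(ZONE), 3.0)
        means_a = means_b + rng.choice([0.0, 2.0], size=len(ZONE))
        a = gen_contact_profile("a", ZONE, means_a, 1.0, rng, n_poses=100)
        b = gen_contact_profile("b", ZONE, means_b, 1.0, rng, n_poses=100)
        fwd = compare_profiles(a, b).flagged
        rev = compare_profiles(b, a).flagged
        assert not (fwd & rev)

    def test_zone_mismatch_rejected(self, rng):
        a = gen_contact_profile("a", ZONE[:3], [1, 1, 1], 1.0, rng)
        b = gen_contact_profile("b", ZONE[3:6], [1, 1, 1], 1.0, rng)
        with pytest.raises(ValueError, match="zone"):
            compare_profiles(a, b)


class TestKeyResidues:
    def test_union_rule_on_printed_highlight_sets(self):
        # the two per-inactive highlighted sets from the calibration panel
        highlighted = {
            "D9M": {res(201), res(202), res(203)},
            "F9M": {res(197), res(198), res(259), res(260)},
        }
        key = KeyResidueSet.from_highlights(highlighted)
        assert len(key) == 7
        assert key.short_names() == ["197G", "198F", "201H", "202A", "203Y", "259P", "260F"]

    def test_no_flags_gives_empty_key_set(self, rng):
        actives, inactives, _ = make_training_panel(
            rng, ZONE, inactive_deficits={"I1": set()}, delta=0.0
        )
        key = derive_key_residues(actives, inactives)
        assert len(key) == 0

    def test_planted_residues_recovered(self, rng):
        actives, inactives, planted = make_training_panel(
            rng, ZONE, inactive_deficits={"I1": {3, 7}, "I2": {3, 7}}
        )
        key = derive_key_residues(actives, inactives)
        assert key.residues == frozenset(planted)
        assert {ZONE[3], ZONE[7]} == set(planted)

    def test_multi_conformer_aggregation(self, rng):
        actives, inactives, planted = make_training_panel(
            rng, ZONE,
            inactive_deficits={"D9M": {5, 6, 7}, "F9M": {1, 2, 12, 13}},
            conformers_per_inactive={"D9M": 5, "F9M": 2},
        )
        key = derive_key_residues(actives, inactives)
        assert key.residues == frozenset(planted)
        assert key.provenance["D9M"] == frozenset({ZONE[5], ZONE[6], ZONE[7]})
        assert key.provenance["F9M"] == frozenset({ZONE[i] for i in (1, 2, 12, 13)})

    def test_invariant_to_ligand_and_conformer_order(self, rng):
        actives, inactives, _ = make_training_panel(
            rng, ZONE,
            inactive_deficits={"I1": {2, 5}, "I2": {5, 9}},
            conformers_per_inactive={"I1": 3, "I2": 2},
        )
        key1 = derive_key_residues(actives, inactives)
        actives_r = dict(reversed(list(actives.items())))
        inactives_r = {
            k: list(reversed(v)) for k, v in reversed(list(inactives.items()))
        }
        key2 = derive_key_residues(actives_r, inactives_r)
        assert key1.residues == key2.residues

    def test_empty_training_side_rejected(self, rng):
        actives, inactives, _ = make_training_panel(rng, ZONE)
        with pytest.raises(ValueError):
            derive_key_residues({}, inactives)
        with pytest.raises(ValueError):
            derive_key_residues(actives, {})


class TestPrediction:
    @staticmethod
    def _key_set():
        return KeyResidueSet.from_highlights(
            {
                "D9M": {res(201), res(202), res(203)},
                "F9M": {res(197), res(198), res(259), res(260)},
            }
        )

    def _query(self, rng, shifted_positions, delta=2.0):
        means = np.full(len(ZONE), 3.0)
        for seq in shifted_positions:
            means[ZONE.index(res(seq))] += delta
        return gen_contact_profile("query", ZONE, means, 1.0, rng, n_poses=100)

    def _actives(self, rng):
        return {
            lab: gen_contact_profile(lab, ZONE, [3.0] * len(ZONE), 1.0, rng, n_poses=100)
            for lab in ("lumcorin", "L9M")
        }

    def test_query_from_active_distribution_is_inhibitor_like(self, rng):
        call = predict_activity(self._query(rng, []), self._actives(rng), self._key_set())
        assert call.is_inhibitor_like
        # only type-I flags possible under the null: always below the
        # half-of-key-set decision boundary
        assert all(len(v) <= 3 for v in call.differing.values())

    def test_two_of_seven_differing_is_inhibitor_like(self, rng):
        query = self._query(rng, [198, 203])
        call = predict_activity(query, self._actives(rng), self._key_set())
        assert call.is_inhibitor_like
        for v in call.differing.values():
            # the two planted residues are always caught (t ~ 14); at most one
            # extra type-I flag keeps the fraction below one half
            assert frozenset({res(198), res(203)}) <= v
            assert len(v) <= 3

    def test_five_of_seven_differing_is_not_inhibitor_like(self, rng):
        query = self._query(rng, [197, 198, 201, 202, 203])
        call = predict_activity(query, self._actives(rng), self._key_set())
        assert not call.is_inhibitor_like

    def test_prediction_is_two_sided(self, rng):
        # key residues engaged *less* by the query still count as differing
        query = self._query(rng, [197, 198, 201, 202, 203], delta=-2.0)
        call = predict_activity(query, self._actives(rng), self._key_set())
        assert not call.is_inhibitor_like

    def test_empty_key_set_rejected(self, rng):
        with pytest.raises(ValueError, match="derive_key_residues"):
            predict_activity(
                self._query(rng, []), self._actives(rng),
                KeyResidueSet(frozenset()),
            )
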