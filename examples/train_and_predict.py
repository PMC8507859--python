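"""Derive key residues from a training panel and classify a query peptide.

Reproduces the calibration logic on planted contact statistics: two
inhibitory peptides (lumcorin, L9M) are compared with two inactive ones
(D9M with five conformer profiles, F9M with two).  D9M under-engages
201H/202A/203Y and F9M under-engages 197G/198F/259P/260F, so the union
rule yields a seven-residue key set.  A query (the cyclic L9Mc) whose
contact pattern differs from the actives at only two key residues is then
predicted inhibitor-like.
"""

import numpy as np

from pepsurf import derive_key_residues, predict_activity
from pepsurf.pose_regions import CATALYTIC_ZONE_RESIDUES, ResidueKey
from pepsurf.synthetic_data import gen_contact_profile, make_training_panel

ZONE = [ResidueKey("A", seq, name) for seq, name in CATALYTIC_ZONE_RESIDUES]

actives, inactives, planted = make_training_panel(
    rng=5, residues=ZONE,
    inactive_deficits={"D9M": {5, 6, 7}, "F9M": {1, 2, 12, 13}},
    conformers_per_inactive={"D9M": 5, "F9M": 2},
    base_mean=3.0, sd=1.0, delta=2.0, n_poses=100,
)

key_set = derive_key_residues(actives, inactives)
print(f"key residues ({len(key_set)}): {', '.join(key_set.short_names())}")
for inactive, residues in sorted(key_set.provenance.items()):
    print(f"  highlighted vs {inactive}: "
          f"{', '.join(sorted(r.short for r in residues))}")

# query engages the zone like an active except at 198F and 203Y
means = np.full(len(ZONE), 3.0)
means[[2, 7]] += 2.0
query = gen_contact_profile("L9Mc", ZONE, means, sds=1.0, rng=6, n_poses=100)

call = predict_activity(query, actives, key_set)
print(f"query {call.query_label}: {call.decision}")
print(f"  {call.rationale}")
print("a query differing at fewer than half of the key residues versus every")
print("known inhibitor is predicted to share their inhibitory activity.")
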