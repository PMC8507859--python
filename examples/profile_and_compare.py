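"""Count receptor-ligand contacts per residue and compare two ensembles.

Profiles two geometric pose ensembles against the 15-residue catalytic
zone (a contact = atom pair closer than 4 A), then screens residue by
residue with the pooled two-sample Student's t-test at alpha = 0.05.
One ensemble hugs the catalytic zone, the other sits 4 A further out, so
the zone residues lose contacts in the second profile.
"""

import numpy as np

from pepsurf import compare_profiles, profile_ensemble
from pepsurf.synthetic_data import (
    gen_pose_ensemble,
    gen_receptor,
    peptide_ca_template,
    region_anchor,
)

receptor, regions = gen_receptor()
zone = regions[0]
anchor = region_anchor(receptor, zone)

template = peptide_ca_template("L9M")
near, _ = gen_pose_ensemble(template, [(anchor, 1.0, 2.0)], rng=3, n_poses=100)
far, _ = gen_pose_ensemble(template, [(anchor + np.array([0, 0, 4.0]), 1.0, 2.0)],
                           rng=4, n_poses=100)

profile_near = profile_ensemble(receptor, near, zone, label="near")
profile_far = profile_ensemble(receptor, far, zone, label="far")

print("residue   mean+-SD (near)   mean+-SD (far)")
for r, mn, sn, mf, sf in zip(zone.residues, profile_near.mean, profile_near.sd,
                             profile_far.mean, profile_far.sd):
    print(f"  {r.short:5s}   {mn:5.2f} +- {sn:4.2f}     {mf:5.2f} +- {sf:4.2f}")

comparison = compare_profiles(profile_near, profile_far)
flagged = sorted(r.short for r in comparison.flagged)
print(f"residues with significantly more contacts in the near ensemble: {flagged}")
print("these are the zone residues whose engagement separates the two binding")
print("modes at p < 0.05 over 100 docking solutions each.")
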