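"""Select docking representatives from a peptide conformer ensemble.

Builds a synthetic trajectory stand-in for the 17-residue lumcorin peptide
with three planted conformations (populations 50/30/20%, 6 A apart, 0.5 A
thermal jitter), then clusters it with the gromos algorithm under the
adaptive 2.2-2.8 A cutoff scan.  The retained cluster centers are the
conformations one would carry into rigid-body docking.
"""

from pepsurf import cluster_ensemble
from pepsurf.synthetic_data import (
    gen_conformer_ensemble,
    make_conformer_templates,
    peptide_ca_template,
)

base = peptide_ca_template("lumcorin")
templates = make_conformer_templates(base, 3, separation=6.0, rng=0)
ensemble, planted = gen_conformer_ensemble(
    templates, fractions=(0.5, 0.3, 0.2), n_models=60, jitter_sd=0.5, rng=1,
    label="lumcorin",
)

result = cluster_ensemble(ensemble)
print(f"ensemble: {len(ensemble)} models of {ensemble.label}")
print(f"cutoff used: {result.cutoff_used:.1f} A")
for i, c in enumerate(result.clusters):
    status = "retained" if c in result.retained else "below threshold"
    print(f"cluster {i}: {len(c):2d} models ({100 * c.fraction:4.1f}%), "
          f"center = model {c.center} [{status}]")
print(f"docking representatives: models {result.representative_indices}")
print("each retained center is one rigid conformation passed to docking;")
print("population fractions estimate how often the peptide adopts it.")
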