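# Methods

This note documents the models and procedures implemented in `pepsurf`,
the defaults chosen where the method leaves room, and what the synthetic
fixtures do and do not establish about real data.

## Problem setting

MMP-14 is a membrane-type matrix metalloproteinase whose catalytic domain
carries two surfaces of interest: the catalytic zone around the active
site (15 residues: 196G–203Y, 236V, 239H, 240E, 243H, 259P–261Y) and the
MT-Loop insertion, a candidate exosite. Short SLRP-derived peptides
(10–17 residues) bind this domain; some inhibit the enzyme. Direct
flexible docking of such peptides is unreliable — their backbone degrees
of freedom exceed what ligand-docking software handles — so the pipeline
follows the rigid-ensemble strategy: sample peptide flexibility first
(conformer ensemble), dock each representative conformation rigidly, and
analyze the resulting pose ensembles statistically.

## Stage 1 — conformer selection

**Model.** Models of an ensemble are compared by RMSD after least-squares
(Kabsch) superposition; the rotation is constrained to det +1 so a mirror
image never superposes onto its enantiomer. Clustering uses the gromos
neighbor-counting scheme: the model with the most neighbors within the
cutoff becomes a cluster center, its cluster is removed, and the count is
repeated on the remainder. Ties take the lowest model index, making the
partition fully deterministic.

**Adaptive cutoff.** The cutoff is scanned from 2.2 to 2.8 Å in 0.1 Å
steps, and the smallest cutoff wins at which the *retained* clusters
(population ≥ 10% of the ensemble) jointly cover ≥ 80% of the models.
The intent is the smallest neighborhood that still concentrates the
ensemble into a few well-populated conformational classes; all four
numbers (range, step, retention 0.10, coverage 0.80) are configurable in
`ClusteringConfig`. If no cutoff reaches the coverage target the result
at 2.8 Å is returned with a warning flag rather than an error, since a
highly heterogeneous ensemble is a legitimate outcome. The fit selection
defaults to alpha-carbons — appropriate for short peptides where
side-chain noise would dominate an all-atom fit; an all-heavy-atom
selection is available.

## Stage 2 — pose localization

Each docked pose is represented by its center of mass (element-weighted
by default; a uniform mode exists for structures with unreliable element
records). The point cloud — canonically the 100 best docking solutions —
is partitioned with PAM (k-medoids) on Euclidean distances.

**PAM implementation.** Deterministic BUILD seeding followed by
steepest-descent single-swap moves. Single-swap descent alone can stall
in configurations where two or three medoids must move simultaneously; we
observed such local optima on roughly 6% of small random instances. The
implementation therefore adds a bounded escape phase — the best
2-medoid (and, on small inputs, 3-medoid) replacement is applied when it
lowers the cost, after which single-swap descent resumes. The procedure
stays deterministic (lowest-index tie-breaks) and, across hundreds of
random instances with n ≤ 10, matched the exhaustive-enumeration optimum
in every case; global optimality is nevertheless not guaranteed in
general, as for any local search.

**Choice of k.** The number of pose clusters is not fixed by the method;
the default selects k ∈ [2, 8] maximizing the mean silhouette width
(ties to the smaller k). Degenerate clouds (one diffuse blob) surface as
a low silhouette in the localization report rather than as an error.

**Region attribution.** Named regions are lists of receptor residues
(chain:number:name selectors, validated against the structure). A pose
cluster is assigned to the region whose heavy atoms come closest to the
cluster medoid's center of mass, or to "other" when that distance exceeds
15 Å — a cap roughly one peptide length beyond direct contact, chosen so
that genuinely nonspecific placements are not force-assigned. Region
credit is per cluster (all member poses inherit it), matching the
cluster-level reading of pose maps; a per-pose mode exists for
sensitivity analysis. Occupancy is the fraction of poses per region and
sums to 1 over regions plus "other".

The catalytic zone ships as a built-in definition. MT-Loop residues are
not hard-coded for real structures — users supply them in the region
file — but the synthetic receptor includes an MT-Loop-like region so the
full path is exercised.

## Stage 3 — contact profiling

A contact is an (receptor-atom, ligand-atom) pair at distance strictly
below 4.0 Å; the strict inequality makes boundary cases deterministic.
Counting is pair-level — one ligand atom near two atoms of the same
residue contributes two contacts — because the downstream statistics
compare contact *numbers*, not binary touch indicators (a binary mode is
provided). Hydrogens are excluded by default on both sides, as docked
poses typically lack them. The k-d-tree implementation is validated
against an all-pairs oracle in the tests. Per-residue means and sample
SDs (n−1) over the pose ensemble form the `ContactProfile` consumed by
stage 4. No distinction is made between hydrophobic and hydrogen-bond
contacts.

## Stage 4 — discriminative statistics and prediction

**Test.** Classical pooled-variance two-sample Student's *t* (df =
n₁+n₂−2), two-sided, α = 0.05, per zone residue, on the pose-level count
columns. Zero-variance degenerate inputs resolve deterministically
(equal means → p = 1; unequal → p = 0, flagged). Welch's test is
available as an option. No multiple-testing correction is applied by
default — the screen covers only 15 residues and feeds a conservative
intersection/union rule — but Benjamini–Hochberg can be switched on for
larger zones.

**Training (key residues).** For an (active, inactive) ligand pair whose
ligands contributed several conformer-level profiles, a residue is a
pair-level hit when it is flagged — significant *and* more engaged by the
active — in at least half of the conformer-by-conformer comparisons
(majority rule; the fraction is configurable). A residue is *highlighted*
against inactive I when it is a pair-level hit for every active versus I;
requiring unanimity across actives suppresses idiosyncratic flags. The
key set is the union of per-inactive highlighted sets: each inactive
peptide may fail to engage a different part of the site, and the union
collects every discriminative position.

**Prediction.** For a query of unknown activity, the direction filter is
dropped: any significant two-sided difference at a key residue counts as
"differing", since both gained and lost engagement depart from the
inhibitor pattern. The query is called inhibitor-like iff, versus every
active reference, (differing key residues)/(key set size) < 0.5. The
one-half threshold is a design choice: it cleanly separates the observed
calibration outcomes (2 of 7 for an inhibitor-like query versus
majorities for dissimilar ones) and is configurable
(`prediction_max_fraction`).

## Synthetic data

The generators emulate the three inputs the pipeline would receive from
molecular dynamics and docking software, with ground truth retained:

- **Conformer ensembles** — template structures deformed by a smooth
  random displacement field, rescaled until all template pairs are at
  least the requested post-fit RMSD apart (default separation 6 Å,
  i.e. ≥ 5× the 0.5 Å jitter used in tests, a margin making planted
  partitions information-theoretically recoverable). Each model is a
  template plus iid Gaussian jitter and a random rigid motion, so
  recovery genuinely requires superposition. Population fractions are
  honored exactly and model order is shuffled.
- **Pose ensembles** — rigid placements of a peptide template with
  centers of mass drawn from a Gaussian mixture anchored at region
  centroids (default spread 2 Å; anchors ~30 Å apart) and uniformly
  random orientations. The mixture weights are the ground-truth
  occupancies.
- **Contact profiles** — per-residue counts drawn as round(N(μ, σ))
  truncated at 0 (default), or Poisson(μ). Defaults μ = 3 contacts,
  σ = 1, n = 100 poses, and planted class effects of Δ = 2 contacts —
  at which the per-comparison t statistic is ≈ 14, so planted effects
  are essentially always detected while the screen's type-I behavior is
  tested separately under the null.
- **Peptide templates** — idealized extended Cα traces (3.8 Å spacing)
  of the five studied sequences, so the real sequence lengths and
  compositions are live fixtures.
- **Receptor** — a deterministic synthetic domain whose catalytic-zone
  residues carry the genuine MMP-14 numbering and names, an MT-Loop-like
  region 30 Å away, and filler residues; four backbone atoms per residue.

All randomness flows through numpy's PCG64 `Generator`; a fixed integer
seed reproduces every fixture bit for bit across platforms.

**What passing tests show — and don't.** Recovery results on this
synthetic data certify the *machinery*: clustering recovers separable
conformational classes, occupancies estimate mixture weights at binomial
accuracy, the t screen is calibrated and recovers planted effects of the
stated size. They do not certify that real MD ensembles are separable at
2.2–2.8 Å, that real docking pose clouds are Gaussian around regions, or
that real contact-count distributions are normal — real counts are
overdispersed, spatially correlated between adjacent residues, and
bounded below by zero in a way the normal model only approximates.
Conclusions about real peptides require real trajectories and docking
runs fed through the same interfaces.

## Numerical choices and edge cases

- Superposition needs ≥ 3 matched non-collinear atoms; fewer raises a
  dedicated error. RMSD matrices are validated symmetric within 1e-9.
- Cluster ordering: decreasing size, then lowest center index; occupancy
  fractions and cluster populations sum to 1 within 1e-12.
- PDB coordinates are written at the standard fixed precision (0.001 Å);
  a read-back reproduces them exactly at that precision. Residue numbers
  are never renumbered.
- Element masses come from the structure library's table; unknown
  elements are reported by symbol rather than silently defaulted.
- Report files contain no timestamps and use sorted keys/fixed ordering,
  making repeat runs byte-identical at a fixed seed.

## Problem sizes used in the validation suite

The shipped tests and the reproduction script run at the study's natural
scale: 100 poses per ensemble, 15-residue zone, 2,000 replicates for the
null calibration, 200 synthetic training panels for recovery rates, 200
random instances for the contact oracle, ensembles of up to 100 models
(and up to 50 for the clustering reference checks). These sizes give
sub-minute runtimes while leaving Monte-Carlo error well below the
thresholds being checked.

## Known limitations

- The pipeline consumes conformer and pose ensembles; it does not run
  molecular dynamics or docking, score poses energetically, or assign
  secondary structure.
- Conformer-level comparisons are unweighted: a conformation's MD
  population does not weight its contact comparisons. Population-weighted
  aggregation is a natural extension.
- Key-residue derivation needs at least one active and one inactive
  ligand and inherits the usual caveats of small training panels.
- PAM's multi-swap escape is bounded; on very large pose sets the search
  reverts to classical single-swap behavior.
- mmCIF, trajectory formats (XTC/DCD) and missing-atom reconstruction
  are out of scope.
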