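# Methods

`tsnap` implements a design–score–prioritize workflow for natural-product-
inspired macrolide libraries: combinatorial assembly of virtual
tetrahydrofuran-containing polyketide macrolides (THF pMLs) from fragment
building blocks, conformer ensemble generation and pruning, Gaussian
shape/pharmacophore similarity scoring aggregated into the C_s statistic,
band-based prioritization for synthesis, macrocycle substituent
descriptors, and the statistics used to call activity in downstream
phenotypic and antibacterial assays.  This note records the models, the
parameters that matter, and the design choices made where the procedure
was genuinely open.

## Library enumeration

Compounds are assembled from three fragment roles.  A *tetrahydrofuranol*
(thf) fragment carries the macrolactone ester oxygen and one olefin
terminus of the ring-closing junction, each encoded as a numbered dummy
atom in its SMILES (`[*:1]` ester, `[*:2]` olefin); it additionally
carries exactly one aldehyde, the precursor of the hydroxymethine
(carbinol) stereocenter.  An *enoate* fragment carries the acyl carbon
(`[*:1]`) and the second olefin terminus (`[*:2]`).  A *side chain*
carries a single `[*:3]` attachment.  Assembly closes the macrolactone
(ester bond + C=C double bond) and converts the aldehyde into a carbinol
bonded to the side chain — mirroring the ring-closing-metathesis and
Nozaki–Hiyama–Kishi disconnections of the laboratory route.

Each fragment triple is expanded into four stereochemical variants: E/Z
at the new macrocyclic olefin and R/S at the new carbinol.  Stereo labels
are *verified*, not assumed: the assembler sets a candidate cis/trans flag
or chiral tag, asks the CIP labeler for the resulting descriptor, and
flips the candidate if it disagrees.  A junction that is not stereogenic
(so the requested label cannot exist) is recorded in the manifest's
skipped log rather than silently dropped; the manifest invariant
`|compounds| + |skipped| = n_thf * n_enoate * n_side * 4` always holds.
Compound ids are `{thf}.{enoate}.{side}.{E|Z}{R|S}`, and the candidate
group key (`thf`, `enoate`, alkene geometry) is invariant to side chain
and epimer, so a full library partitions into groups of six.

All stereocenters other than the carbinol are inherited verbatim from the
block SMILES.  The toy fragment generator leaves ring stereocenters
unspecified; this is deliberate (it keeps the toy pool small and the
enumeration count structure exact) but means toy compounds are stereo-
underspecified relative to real building blocks.

## Conformer ensembles

`sample_ensemble` runs an iterated heat-then-quench chain: short
molecular dynamics at high temperature followed by gradient minimization,
each iteration starting from the previous minimized geometry.  Defaults
are the production protocol — 2500 iterations of 1 ps at 1000 K with a
1 fs timestep, minimization to an RMS gradient of 0.01 kcal/mol/Å —
although tests and examples use far shorter chains on small molecules.

* **Potential.**  Any deterministic `energy`/`gradient` provider
  satisfying the `ForceFieldBackend` contract can drive the chain.  The
  production backend wraps RDKit's MMFF94.  Generalized-Born solvation is
  not available there; the solvent dielectric of 78.3 is folded into
  MMFF's distance-dependent dielectric model instead.  (The source
  protocol names both a GB/Still model and a distance-dependent
  dielectric of 78.3, which are normally exclusive; we implement the
  latter and record the ambiguity here.)  A harmonic `QuadraticBackend`
  exercises the machinery in tests.  One hard-won practical constraint:
  RDKit's `ForceField.CalcGrad` reuses terms cached by the most recent
  `CalcEnergy` call, so the backend always evaluates the energy at the
  same coordinates immediately before requesting the gradient; without
  this the MD forces are corrupted and the integrator heats
  catastrophically.
* **Integrator.**  Velocity Verlet with Berendsen velocity rescaling
  (coupling time 100 fs, per-step scale factor clamped to [√0.5, √2]).
  Initial velocities are Maxwell–Boltzmann; iteration *k* draws them from
  `SeedSequence([seed, k])`, so one integer seed reproduces the whole
  chain and iterations are independent of execution order.
* **Restraint.**  Double-bond torsions are restrained by a one-sided
  harmonic, `k·(|Δτ| − 45°)²` for deviations beyond 45° from the ideal
  (0° or 180°, snapped from the starting geometry), with
  k = 0.005 kcal/deg² by default (valid range 0.005–0.01).  The boundary
  is strict: a deviation of exactly 45° incurs zero penalty.  The
  restraint acts during MD and minimization only; conformer energies and
  the retention window below are *unrestrained* backend energies.
* **Stereochemistry enforcement.**  After each minimization, double-bond
  torsions more than 90° from ideal or chiral centers whose signed volume
  flipped mark the conformer as inverted; it is discarded and counted.
  Non-converged minimizations are likewise excluded rather than kept at
  their last gradient.
* **Pruning.**  `filter_energy_window` retains conformers within
  15 kcal/mol of the ensemble minimum (boundary inclusive; the minimum
  always survives).  `deduplicate_rmsd` sweeps in ascending energy and
  keeps a conformer only if its heavy-atom Kabsch RMSD to every
  already-kept conformer is at least 0.50 Å — the greedy-from-minimum
  reading of pairwise deduplication, which guarantees the global minimum
  survives and makes the result order-independent.  RMSD uses heavy atoms
  only (hydrogen positions at 1000 K are noise); superposition is
  delegated to `scipy`'s `Rotation.align_vectors`.

`embed_ensemble` offers a fast distance-geometry alternative (seeded
ETKDG embedding + MMFF minimization + dedup) for scoring work where the
MD chain would be overkill; examples and the similarity-recovery tests
use it.

## Shape and colour overlap

The similarity engine is a first-order Gaussian ROCS analogue.  Each
heavy atom contributes an isotropic Gaussian of amplitude p = 2.70 whose
exponent is chosen so it integrates to the atom's hard-sphere volume
(Bondi radii).  Molecular overlap is the sum of closed-form pairwise
product integrals — the first-order (pairwise) truncation of the
inclusion–exclusion series.  This truncation is a known systematic
difference from hard-sphere volumes (a single carbon's self-volume sits
about 4.5 % below 4πr³/3) but is exactly integrable, and a brute-force
grid integrator over the same density (`grid_overlap_oracle`) converges
to the closed form as the spacing shrinks, which the tests exploit.

Colour features are typed by an explicit, versioned substructure table
(donor, acceptor, cation, anion, hydrophobe, ring) documented in
`tsnap/color.py`; it is an in-repo approximation of the proprietary
Mills–Dean scheme.  Ionizable groups claim their atoms first (a carboxyl
group is one anion feature; its oxygens are not double-typed as
donor/acceptor), ring features sit at the centroids of 5–7-membered
rings, and hydrophobes at centroids of ≥3-carbon aliphatic clusters with
no heteroatom neighbours.  Features are spherical Gaussians of radius
1.0 Å and overlap only within a type.

`optimize_overlay` centers both models at their volume-weighted
centroids, aligns principal axes of the weighted inertia tensor,
enumerates the four proper axis flips, and from each start locally
maximizes the summed shape + colour overlap (weights 1:1) over the six
rigid degrees of freedom with Nelder–Mead (tolerance 1e-4, fixed
iteration cap, plus one polishing restart from the winner).  The result
is deterministic, never worse than the best unoptimized start, and
recovers planted rigid transforms of asymmetric shapes to within 5°.
Scores are shape Tanimoto `V_AB/(V_AA+V_BB−V_AB)`, colour Tanimoto
(same form on colour overlaps; defined as 0 when either feature set is
empty), and their sum "combo" ∈ [0, 2].  Bit-compatibility with
proprietary GPU implementations is a non-goal.

## The C_s statistic

For one query compound and one reference, every query conformer is
overlaid on every reference conformer, giving a combo-score matrix.  For
each *reference* conformer the best query match is kept; these top
matches are averaged over the reference's conformers and divided by two,
normalizing C_s to [0, 1] with self-similarity at the ceiling.  The
aggregation direction follows the procedure's top-match-per-reference-
conformer description; because the source narrative also mentions
query-side maxima, a `symmetric=True` mode averages both directions'
means before normalizing.  Scoring a query against a reference panel
yields one C_s per reference; the largest (C_s^max) and its reference id
form the prioritization currency.

## Prioritization

Compounds sharing a backbone key form a candidate group (six members in
a full library).  A group is selected when at least one member's C_s^max
lies inside a closed band, default [0.55, 0.70]: the lower bound demands
genuine resemblance to the natural-product reference set, the upper
bound excludes near-replicas of it.  Every member of a selected group
becomes a synthesis target — the untriggered members diversify the
backbone.  Partial groups are permitted (flagged incomplete) so toy
libraries run end to end.  The final manual refinement of selected
groups down to a minimal building-block set is intentionally not
automated; `coverage_report` tabulates the block usage a chemist needs
for that step.

## Assay statistics

* **Dilution series** are exact geometric sequences; a 16-point two-fold
  series from 128 µM ends at 3.90625 nM (printed 3.91 nM).  The
  analogous published 96 µM → "1.5 nM" series is internally inconsistent
  (16 two-fold steps from 96 µM end at 2.93 nM); the package computes
  the arithmetic and leaves the discrepancy visible.
* **Fingerprint filtering** removes, per concentration slice, any feature
  column containing a value above `median + 3·SD` (sample SD over that
  column in that slice).  Removal is slice-local (masked to NaN).  Note
  a structural property of this rule: a single outlier inflates its own
  column SD, so it is only detectable when the slice has more than ~10
  wells — with five wells no single outlier can ever be flagged.
* **Activity scores** are Euclidean norms of filtered fingerprints
  (NaN-masked features ignored); a concentration is active when its
  score exceeds five times the mean negative-control score.  The
  five-times-*median* variant also circulates for this threshold; mean
  is the default and `center="median"` the flag.
* **MTT viability** is `100·(A − mean(background)) / mean(DMSO −
  mean(background))`.
* **MIC** is read from OD600 endpoint growth (t20 − t0, blank-subtracted,
  vehicle-normalized): the lowest concentration reaching ≥90 %
  inhibition with all higher concentrations also above the cut — a
  CLSI-style full-inhibition reading; series never reaching the cut are
  censored as greater-than the maximum tested.  Single-point percent
  inhibition is the linear interpolation between blank (100 %) and
  vehicle (0 %), clamped above at 100 %, with growth promotion reported
  as negative values.

Concentrations are micromolar throughout; nanomolar appears only in
display strings.

## Macrocycle descriptors

The backbone is the largest smallest-set-of-smallest-rings ring of size
≥ 12, ties broken by most ring oxygens (the ester-bearing ring) and then
canonical atom order.  *Substituents* are all other heavy atoms — side
chains, exocyclic carbonyl oxygens, and unfused atoms of embedded small
rings alike; atoms shared between the macrocycle and a fused ring belong
to the backbone.  The descriptor axes are the substituent share of heavy
atoms, the N/O/S fraction of substituent atoms (halogens count
nonpolar; configurable), and Wildman–Crippen cLogP (delegated to RDKit;
cross-checked in tests against Open Babel's independent implementation
of the same published parameterization).

## Synthetic fixtures: what they emulate and what they do not

The real building blocks and reference structures exist only as drawn
figures, so `tsnap.fixtures` generates structural stand-ins.
`toy_building_blocks` produces chemically valid fragments (≤ 12 heavy
atoms; enoate chains of ≥ 4 methylenes keep the assembled macrolactone
at ≥ 12 atoms) whose counts mirror the real pool — 9/32/3 enumerates to
exactly 3456 compounds in groups of six.  `toy_reference_set` assembles
reference macrolides from reference-only enoate fragments, so unplanted
references never coincide with library members; an optional planted
reference duplicates one library compound and provides ground truth for
similarity-recovery tests.  `synth_assay_plates` draws negative-control
fingerprints from an independent unit-normal null, scales planted
actives by a multiplicative effect size (default 10), plants MIC steps
into growth curves, and emits a truth sidecar.  Everything is seeded and
regenerates byte-identically.

Passing tests on these fixtures demonstrates the *logic* — counting,
stereo enumeration, filtering rules, aggregation arithmetic, threshold
calls, rank recovery under planted signal — not chemical realism: toy
conformational energetics are not polyketide energetics, the fingerprint
null has none of the feature covariance of real morphological profiles,
and absolute C_s values for toy compounds do not transfer to the real
library (reproducing its reported C_s range is out of scope, since the
real structures and the proprietary scoring engine are unavailable).

## Problem sizes used in the shipped checks

The test and acceptance runs use desk-scale sizes chosen to exercise
every code path: full-scale enumeration (3456 compounds) but toy-scale
conformer chains (tens of iterations, ≤ 0.2 ps segments), 48-compound
libraries with 2-conformer ensembles for similarity recovery, 100-seed
null calibrations for assay calls, and 100-trial pose-recovery batches.
The production-scale protocol parameters remain the defaults on
`SamplingConfig`.

## Known limitations

* First-order Gaussian volumes undercount dense overlaps; scores are
  comparable within this engine, not across engines.
* The colour table is an approximation of an unpublished scheme; feature
  definitions are versioned so scores are reproducible, not canonical.
* The MD chain is a conformer generator, not a thermodynamically faithful
  1000 K ensemble (Berendsen rescaling, no constraint algorithm).
* E/Z and R/S assembly requires the junctions to be CIP-stereogenic;
  degenerate toy fragments are skipped with a reason rather than
  enumerated.
* `mic_from_curves` assumes endpoint OD600 readings; full growth-curve
  kinetics (lag/log-phase fitting) are out of scope.
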