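# Methods

## Problem and scope

Focal cortical dysplasia (FCD) is a developmental malformation of cortical
organization and a leading cause of refractory focal epilepsy; lesions in
the central (sensorimotor) region are frequently invisible on conventional
MRI reading ("MR-negative"). Because FCD arises during sulcal
morphogenesis, it leaves a morphological signature on the folds themselves
— broadening, increased depth, altered orientation, disrupted relations
with neighbouring sulci. This package implements a sulcus-based anomaly
analysis of that signature: attributed sulcal graphs of the central region
are labeled automatically by energy minimization against a normative
control model, the labeling objective is decomposed into per-sulcus local
energies ("sulcus energy"), patient energies are standardized against
control variability ("sulcus energy z-score"), and the most abnormal
sulcus of the hemisphere ipsilateral to the suspected lesion is evaluated
as a localization call with a within-patient permutation test, an exact
Poisson-binomial null, and a sulcus-wise ROC.

Upstream image processing (tissue segmentation, fold skeletonization) is
out of scope: a synthetic generator produces sulcal graphs with the
statistical structure the analysis assumes, and a packaged annotation
table of a published 28-patient surgical cohort (per-patient FCD sulci,
lesion side, MR status) supplies the real-data inputs for the localization
statistics.

## Sulcal graphs

One graph per hemisphere. Nodes are elementary folds of a fixed 13-sulcus
central-region nomenclature (central sulcus S.C.; postcentral, precentral
and frontal neighbours; the ramifications S.C.sylvian, S.C.LPC, S.p.C),
each carrying area (mm²), maximal depth (mm), length (mm), centroid (mm,
right-handed frame with origin at the hemisphere centroid — the method
needs no inter-subject registration) and a unit orientation vector. Edges
are typed relations: direct junction, neighbourhood geodesic to the brain
hull, or a split induced by a buried gyrus (with the gyrus depth as an
extra attribute); each relation carries a contact direction, an involved
volume (mm³) and a minimum distance (mm). Orientation-like vectors are
sign-ambiguous — a fold has no intrinsic direction — so every comparison
uses the absolute cosine. Right-hemisphere graphs are mirrored (x negated)
into the left frame before any statistic is computed, so one normative
model serves both hemispheres.

## Normative model and energy

The control model holds, per label, the sample mean and covariance of the
6-dimensional scalar descriptor (area, depth, length, centroid), a
sign-invariant mean orientation (principal axis of the orientation scatter)
with an angular SD, and, per (label-pair, relation-type), the analogous
relation statistics plus the frequency `f` with which control hemispheres
exhibit the relation. Covariances are regularized by adding
`eps = 1e-3 x mean(diag(cov))` (floored at 1e-6) to the diagonal; angular
SDs are floored at 1e-3 rad. These floors only matter for degenerate
(zero-variance) training sets.

The labeling energy is a sum of non-negative local terms, so zero means a
perfect match to the control template:

* node potential: `1/2 (a - mu)' Sigma^-1 (a - mu) + 1/2 (theta/sigma_theta)^2`,
  with `theta` the absolute-cosine angle to the mean orientation; a fold
  labeled background costs `lambda_background`;
* edge potential (both endpoints labeled): the same quadratic form on the
  relation attributes and contact direction, plus `max(-log f, 0)`;
  a relation controls never exhibit between those labels costs
  `lambda_spurious`; relations touching a background fold carry no
  normative information and cost nothing;
* missing-relation penalty: every modelled relation that is not realised
  while **at least one** of its endpoint labels is assigned costs
  `lambda_missing`. Charging one-sided breaks is deliberate: if the
  penalty required both endpoints, unlabeling a well-connected sulcus
  would silently delete all its relation terms, making background
  labelings globally optimal. With the one-sided rule, backgrounding a
  correct fold always costs more than labeling it.

Defaults: `lambda_missing = lambda_spurious = 3.0`,
`lambda_background = 10.0`. The penalties must exceed the typical energy
of a correctly labeled fold (expected node term ~3 for 6 descriptors, plus
half-shares of its relation terms, ~5-6 in total; more for the
well-connected central sulcus); 10.0 satisfies that with margin while
keeping background feasible for genuinely aberrant folds.

The total decomposes exactly into per-sulcus local energies: each node
keeps its own potential, every pairwise term is split half-and-half
between its endpoint labels, and a one-sided missing penalty goes entirely
to the assigned endpoint. The sum of local energies equals the total by
construction (checked to 1e-9 relative in tests).

## Recognition

Labels are assigned by Metropolis simulated annealing over single-node
relabel moves (13 labels + background), starting from all-background,
with duplicate non-background labels excluded by move rejection. Schedule:
geometric cooling, `T0 = 5`, `gamma = 0.95`, 20 full-graph sweeps per
level, `T_min = 0.01`; each proposal is evaluated by an exact incremental
energy delta (node term, incident edges, affected missing-relation terms).
The best labeling visited is returned with its exactly recomputed total
energy. Reliability follows the best-of-k rule (`k = 10` by default): the
k runs differ only by derived seeds; group analyses keep the run with the
lowest central-sulcus local energy, individual analyses the run with the
lowest summed central-region energy, with ties broken by total energy and
run index. An exhaustive branch-and-bound minimizer over graphs of at most
6 nodes serves as the test oracle; the annealer matches its optimum on
>= 95% of random small graphs and can never return a lower energy.

At the default schedule one annealing of a 13-node hemisphere takes ~50 ms,
and best-of-10 labeling accuracy on default-noise cohorts is ~99%.

## Z-scores and localization

Control energy maps give a per-(hemisphere, label) mean and SD (n-1
denominator; cells with fewer than 2 controls are omitted); a patient's
z-score is `(E - mean)/max(sd, 1e-6)`, sulcus by sulcus. Patients never
enter the normative statistics. Localization considers only the central
region of the hemisphere ipsilateral to the (electroclinically lateralized)
lesion and calls the sulcus with the maximum z; exact ties go to the
alphabetically first label and are flagged.

The hit count over patients is tested against the within-patient
permutation null: permuting the FCD indicator over a patient's
`n` candidate sulci hits the fixed max-z sulcus with probability `k/n`
(`k` = number of FCD sulci), so the null statistic is a sum of independent
Bernoullis. The Monte-Carlo p-value is `(1 + #{perm >= obs})/(1 + N)` with
`N = 10 000` (probabilities sorted first, making the draw invariant to
patient ordering); the exact upper tail of the Poisson-binomial
distribution, computed by dynamic programming, is used as the oracle.
For the published cohort all patients are given 13 candidate sulci, per
the fixed central-region nomenclature. The sulcus-wise ROC pools all
scored ipsilateral central-region sulci over patients, calls a sulcus
positive when `z >= threshold`, and integrates trapezoidally.

Group-level comparison of central-sulcus energies is a covariate-adjusted
OLS (age, sex, field strength, plus hemisphere or lesion side) with the
group term tested by a nested-model F test, run per hemisphere, on subject
means, and in ipsilateral/contralateral form (patients contribute the
lesion-side or opposite hemisphere, controls both hemispheres with a
hemisphere cofactor). A repeated-measures multivariate analysis would need
the original cohort's correlated bilateral data to be meaningful; with the
generator's independent hemispheres the OLS F test is exact, and its
type-I error and power are the tested contract.

## Synthetic generator

The generator emulates what fold extraction yields for the central region:

* a 13-sulcus template with realistic attribute magnitudes and a Fig-style
  topology (S.C. geodesic neighbour of the nine surrounding sulci,
  junctions to its three ramifications, a precentral chain with one
  buried-gyrus split, 19 expected relations in all);
* label-specific variability: every SD scales with a per-label factor
  rising strictly from 0.6 (S.C., the most stable sulcus across
  individuals) to 1.8 (S.C.sylvian, the most variable). Base SDs at factor
  1: 10%/8%/10% relative for area/depth/length, 3 mm centroid, 8 deg
  orientation; relation attributes 20%/30% relative, 10 deg direction;
* occasional absence of the minor ramifications (presence 0.9 for
  S.C.sylvian, S.C.LPC, S.p.C; 1.0 elsewhere — the central sulcus is
  always present); relations are instantiated iff both endpoints exist;
* Gaussian attribute noise truncated to positivity (the truncation
  virtually never binds at the default SDs); orientation noise as an
  exact-angle rotation about a random perpendicular axis;
* FCD perturbation of 1-3 target sulci per patient (counts drawn with the
  empirical frequencies 16/28, 7/28, 5/28 of the reference cohort; targets
  grown over template adjacency, since lesions sit in the vicinity of
  several neighbouring folds): depth and area shifted by exactly
  `delta x SD(label)`, orientation rotated by exactly `delta_theta`, each
  relation touching a target dropped or retyped with the disruption
  probability. Defaults `delta_depth = delta_area = 2.0` SD,
  `delta_theta = 30 deg`, disruption 0.25 — a visually notable abnormality
  (~98th percentile of control variability), chosen once as the simulated
  study condition;
* covariates (age ~ U(18, 45) years, sex 50/50, 30% at 3 T, lesion side
  50/50) with zero effect on morphology by default; nonzero depth effects
  are accepted for confounding/power studies. Both hemispheres are
  generated per subject; the contralateral hemisphere is never perturbed.

What the generator does **not** emulate: MR intensities and the visual FCD
criteria (thickening, signal changes, blurring), segmentation artifacts,
spurious/extra folds (so background is never the true label), correlated
bilateral anatomy, covariate effects on morphology, and the real,
unpublished control variability — the template magnitudes are calibration
choices. Passing tests therefore demonstrate the internal consistency and
statistical calibration of the method under its own assumptions, not its
clinical sensitivity on real MRI.

## Calibration properties (tested)

* Energy decomposition conserves the total on 500 random labeled graphs.
* Leave-one-out control z-scores: per-label |mean| < 0.2 and SD in
  [0.8, 1.25] over 110 controls.
* Under the null (unperturbed patients), the localization p-value is
  uniform over 200 replicate cohorts. The permutation p is discrete
  (Poisson-binomial support), so uniformity is asserted for the
  standard randomized version `P(X > obs) + U x P(X = obs)` computed with
  the exact oracle — the calibration statement appropriate to a discrete
  test; the reported p-value keeps the conservative `(1+b)/(1+N)` form.
* The max-z sulcus hits a random 3-label subset at rate 3/13 under the
  null; pooled ROC AUC is ~0.5 under the null and well above 0.5 at the
  default lesion signature.
* The ipsilateral group test holds its nominal level (rejection rate in
  [0.035, 0.065] at alpha = 0.05 over 1000 null cohorts of 29 + 29) and
  exceeds 50% power at the default effect size.
* Generator and pipeline outputs are bit-for-bit reproducible under fixed
  seeds.

Statistical calibration runs use energy maps computed from the generator's
true labels: this separates the statistical contract from recognition
noise (recognition quality is tested separately against the exhaustive
oracle and by labeling accuracy) and keeps replicate counts high at
moderate cost. Problem sizes used by the test-suite and analysis scripts —
29+29 study subjects, 50 training controls, 100-200 replicate cohorts,
10 000 permutations (10^6 for the oracle-agreement check), best-of-10
recognition on a 12-hemisphere subsample — are the package's chosen
simulation scale.

## Known limitations

* The energy potentials are a fully specified Gaussian stand-in for the
  original learning-database potentials; absolute energy values are not
  comparable to the original system, only their normalized (z-score) form.
* With small subgraphs, many expected relations break by construction and
  the background label can legitimately win — exhaustive-oracle tests on
  tiny graphs compare solvers against each other, not against anatomy.
* `n_candidates` is fixed at 13 for the published cohort; if a patient's
  sulci were incompletely labeled in the original data the per-patient
  candidate counts would differ slightly. Records computed from synthetic
  z-maps use the actually scored sulci.
* The group comparison treats hemispheres as independent observations,
  which is exact for the generator but would understate within-subject
  correlation on real data.
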