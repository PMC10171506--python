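# Methods

This note documents the models, numerical choices and limitations of the
package in one place: what the scores compute, what the synthetic cohort
emulates (and what it does not), and the design decisions taken where the
design was genuinely open.

## The scores

Both scores reduce a subject's whole-brain first-level contrast map to a
single number measured against a young reference sample.

**FADE** is the mean t-value over analysis-mask voxels *outside* the young
activation set J⁺ minus the mean t-value *inside* J⁺. A subject whose
activation is concentrated where young adults activate scores low
(negative); a subject whose response is diffuse or displaced scores high.
"Outside J⁺" means analysis-mask voxels not in J⁺ — off-mask voxels carry
no statistic and are never summed. The score needs a non-empty J⁺;
building a reference whose positive mask is empty is an error.

**SAME** standardizes each voxel's deviation from the young mean by the
young between-subject SD and averages with opposite sign conventions over
J⁺ and J⁻, so that both weaker activations and weaker deactivations lower
the score. The two terms are kept available separately as activation and
deactivation components; their sum is the score. If the reference has no
significant deactivations, the deactivation term is 0 and a
`deact_defined` flag is carried through every downstream table rather than
raising an error, because the activation-based information remains valid.

Young subjects are scored against the full young reference, themselves
included — the published usage of such scores. A leave-one-out option
(`score_cohort(..., leave_one_out=True)`) rebuilds the reference per young
subject from the remaining young maps; it is off by default.

Exact properties used as test anchors: SAME is linear in the interpolation
between a subject's map and the young mean, `SAME(a·γ̂ + (1−a)·β̂) =
a·SAME(γ̂)`; SAME = 0 when γ̂ ≡ β̂; FADE = 0 on an all-zero t map; and
SAME = activation + deactivation component whenever the latter is defined.

## Reference construction

The young reference is a voxel-wise one-sample t test of the young
contrast-estimate stack (df = n−1). Voxels with zero between-subject
variance yield non-finite t values; NaN (0/0) never passes thresholding,
±∞ (nonzero mean, zero variance) counts as maximally significant in its
tail. Family-wise voxel correction is **Bonferroni over analysis-mask
voxels**, not random-field theory: it needs no smoothness estimate, it is
conservative, and its error control is exactly testable by simulation.
This is a deliberate deviation from common fMRI practice and is part of
the package's contract. Both tails use the same α and the same extent
threshold; connectivity for the k-voxel extent rule defaults to 26
(full-corner neighborhoods) and is configurable to 6 or 18.

Voxel-wise regressions of maps on a per-subject score use cluster-level
inference by permutation: per-voxel simple-regression t, clusters formed
among voxels exceeding the uncorrected cluster-forming threshold
(*p* < .001 one-tailed by default), and a cluster's family-wise p computed
from the permutation null of the maximum cluster size (score labels
permuted across subjects, 1000 permutations by default). On spatially
independent noise the maximum-cluster-size statistic is extremely discrete
(clusters are almost all singletons), which makes the procedure far more
conservative than its nominal level; on spatially smooth maps — the regime
cluster inference is meant for, and the regime of real contrast maps — the
empirical family-wise rate sits at the nominal .05 within simulation
error. The calibration simulations therefore use smoothed null maps.

## Synthetic cohort

The generator works at "effective regressor" level: it draws
contrast-estimate maps directly, with no time-series simulation or
hemodynamic convolution, because the scores consume contrast maps and the
first-level module is exercised by its own small fixtures.

* **Geometry.** Signal clusters are spheres on the lattice (center,
  radius, amplitude); amplitudes add where spheres overlap. Spheres are
  trivially reproducible and give exact control over cluster extent for
  testing the k-voxel filter. The memory contrast re-uses the novelty
  geometry with reproducibly jittered centers so the two contrasts are
  related but not identical.
* **Maps.** A young subject's map is the cluster template plus white
  Gaussian noise (`noise_sd`, default 1.0 with cluster amplitudes of
  about 1 — effect sizes around one between-subject SD). An older
  subject's map is `(1−α)·activations + (1−δ)·deactivations + noise`,
  with α (activation attenuation) and δ (deactivation reduction) drawn
  per subject from truncated normals on [0, 1]. Defaults: α ~ N(.35,
  .20²), δ ~ N(.45, .20²) truncated — moderate, variable attenuation with
  somewhat stronger loss of deactivation.
* **t maps.** Each subject's t map is the γ̂ map divided by a per-subject
  residual-scale estimate drawn as a chi-distributed estimate of
  `noise_sd` with `t_dof` degrees of freedom (default 100), so t and γ̂
  are proportional within subject — the relation the FADE equation
  assumes — without fitting a GLM per voxel.
* **Behavior.** A latent memory ability drives all behavioral outputs.
  For older subjects it tracks the *preserved* signal,
  `ability = coupling · [(1−α) + w·(1−δ)]/(1+w) + ε` with
  `w = deactivation_coupling` (default 1) and ε ~ N(0, 0.2²). Coupling
  ability to the deactivation parameter as well as the activation
  parameter gives the SAME score a channel of behavioral information that
  FADE (which barely sees J⁻) lacks — the same mechanism the scores'
  deactivation components are designed to capture. Recognition ratings
  come from an equal-variance latent-Gaussian model: new items draw
  strength from N(0,1), old items from N(d,1) with d = max(ability, 0),
  discretized by four fixed criteria (−1.5, −0.5, 0.5, 1.5) into the
  5-point scale. Zero ability gives identical old/new distributions and
  chance A′.
* **Battery.** The 19-variable neuropsychological battery is generated per
  variable as group-anchor mean + SD · (direction · loading · z + noise),
  where z is the subject's ability standardized within group. The default
  anchors are the study-scale group summary cells of the published
  battery; memory variables load 0.6 on ability, speed/attention variables
  0.35, with reaction-time and error variables pointed downward. Cells go
  missing independently (3% default) and extreme outliers can be planted
  for testing the exclusion rule.

What the generator does **not** emulate: anatomy and template space,
spatial autocorrelation of the noise (maps are voxel-wise independent),
physiological noise, scanner and session effects, and any nonlinear
relation between attenuation and behavior. Passing tests therefore
demonstrate correctness and calibration of the *procedures* under the
generative model's assumptions, not performance claims about real cohorts.

## Statistics

* **Group comparisons** are independent-samples t tests (the young and
  older groups are different people), pooled (Student) or Welch, with an
  "auto" form that uses Welch when Levene's test (mean-centered variant)
  is significant at .05. The summary-statistics path computes identically
  from (mean, SD, n) triples, which is what allows recomputing printed
  table statistics from printed cells.
* **A′** is the area under the empirical ROC traced by cumulative hit and
  false-alarm rates at rating criteria 5, 4, 3, 2 with the (0,0) and (1,1)
  endpoints, trapezoidal rule. This equals the pairwise concordance
  P(r_old > r_new) + ½·P(r_old = r_new), which the test suite uses as the
  normative oracle. It is not the classic Snodgrass A′ formula.
* **Outlier rule**: a value is excluded iff x > Q3 + 3·IQR or
  x < Q1 − 3·IQR, strict inequalities, quartiles by linear interpolation
  of order statistics ("type 7") — the convention is pinned because the
  exclusion set depends on it. Applied separately per age group; missing
  values pass through.
* **Dependent correlations** are compared with the Meng–Rosenthal–Rubin z
  test.
* **Regression families** (one per contrast and analysis, five models
  each) are ordinary least squares with intercept; per-coefficient t tests
  give each score's unique contribution, and Holm–Bonferroni step-down
  correction is applied to the family of model p values. Rows are
  pairwise-complete per model. A condition-number guard (10¹⁰) rejects
  collinear predictor pairs.
* **Stepwise LDA** minimizes Wilks' Λ = det(W)/det(T) by greedy forward
  selection with partial-F gates, default F-to-enter 3.84 and F-to-remove
  2.71 — the conventional stepwise defaults, since only the Λ-change
  stopping rule itself is part of the specification — with a removal pass
  before each entry. Complete cases only. The discriminant function is
  scaled to unit pooled within-group variance and oriented so the
  lexicographically last class (young above older) scores high;
  standardized canonical coefficients use pooled within-group SD scaling.
  Classification is nearest-centroid in discriminant space with equal
  priors, reported in-sample overall and per group. The per-subject
  discriminant score is exported as the global-cognition composite.
  Significance of the final Λ uses Bartlett's χ² approximation.

## Numerical choices and degenerate inputs

Rating-to-modulator mapping is r ↦ arcsin((r−3)/2), then mean-centering:
the 5-point scale spans arcsin's full domain [−1, 1], weighting the
confident ends more than a linear recode; the exact scaling used by other
implementations is not standardized, so this convention is stated here as
an assumption. First-level OLS propagates non-finite t values at
zero-residual-variance voxels (residuals at the rounding level of the data
count as zero) instead of silently zeroing them; downstream masks exclude
them. Cluster coordinates are 0-based voxel indices; world coordinates
exist only through the stored affine. All randomness flows from one root
seed through named substreams per stage, and re-running a pipeline with an
unchanged configuration reuses cached stage outputs (hashes in the run
manifest make this checkable).

## Problem sizes

Simulation-based checks run at desk scale, chosen to keep the full suite
in minutes while leaving the statistical questions intact: grids of 10–16
voxels per axis (1 000–4 096 voxels), cohorts of 12–210 subjects,
100–1 000 simulation replicates and 200 permutations per cluster test.
Parameter-recovery runs use 60 young and 150 older subjects — the older
group at the scale of the study design the pipeline targets. The
default `CohortSpec` (106 young, 153 older, 20³ grid) mirrors that design
directly and runs in seconds per cohort.

## Known limitations

Bonferroni is conservative relative to random-field-theory FWE at matched
α, so reference masks are smaller than an SPM-style analysis would give on
the same data. The permutation cluster test is conservative on unsmoothed
maps (see above). The stepwise-LDA entry gate at 3.84 admits occasional
noise variables in large samples — inherent to stepwise selection at a
fixed F — so selection results should be read as a screening device, which
is also how the global-cognition composite uses them. Scores for young
subjects include themselves in the reference by default, which biases
young SAME scores toward 0 (exactly 0 on average) — the leave-one-out
option exists where that bias matters. Cross-cohort reference
harmonization (scoring against a reference built from a different young
sample) is out of scope.
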