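# Methods

## Study design being modelled

The pipeline reproduces the derivation and validation of a clinical
prediction rule for pediatric growth hormone deficiency (GHD).  Children
are included because they met the Growth Hormone Research Society (GHRS)
auxologic criteria for a GH stimulation test (GHST); GHD status is then
ascertained from the maximal stimulated GH peak with an era-dependent
cut-off (< 6.1 ng/ml for tests in 2004–2011, < 4.7 ng/ml from 2012 —
the assay standard changed between eras).  The era boundary is
implemented as a configurable table with the 6.1 cut-off applying through
calendar year 2011 and 4.7 from 2012 on; children weighing ≥ 10 kg
require two sequential test arms (arginine, clonidine), a single arm
suffices under 10 kg.  All thresholds are applied with the strict
inequalities of their operational definitions.

Fifteen dichotomous risk predictors are derived from raw clinical
measurements.  They are tri-state (`True`/`False`/missing) at the data
layer: in particular, pituitary dysgenesis (≥ 2 of anterior hypoplasia or
aplasia, interrupted/hypoplastic stalk, ectopic/absent posterior lobe) is
*missing*, never false, when no MRI was performed.  Policy about
missingness belongs to the consuming layer: the clinical rule treats
missing as not-satisfied (conservative toward a negative call, because a
false positive means unnecessary GH treatment), and the tree learner has
its own policy described below.  "Signs of an intracranial lesion",
"signs of multiple pituitary hormone deficiency" and "neonatal GHD signs"
have no operational definition and are accepted as boolean inputs to the
eligibility screen.

## Association statistics

Each predictor is summarised against GHD status in a 2×2 table.  All
predictors use the full cohort as denominator with missing counted as
predictor-negative, except pituitary dysgenesis, which is tabulated on
the MRI-assessed subset only (the flag is undefined elsewhere).

The point odds ratio is `ad/bc`.  Finite-cell intervals default to the
Woolf log-interval; a Haldane–Anscombe (+0.5) corrected interval and an
exact conditional interval (tail inversion of the noncentral
hypergeometric distribution, via scipy's conditional odds-ratio) are
also available.  Zero-cell tables report 0 or ∞ as the point estimate
with the finite bound from exact conditional inversion; the exact
implementation is cross-checked in the test suite against a brute-force
enumeration of the conditional distribution.  The interval method behind
historical printed tables of this design is not identifiable from the
point estimates; the package therefore exposes all three and asserts
only the point estimates in hard tests.

Association p-values default to Pearson's chi-squared without continuity
correction; Fisher's exact test is provided and is the method that
reproduces printed p-values on sparse tables of this design (the
asymptotic test is unreliable there).  A table with a zero margin has no
defined statistic: the low-level function raises, and the table-level
report records the p-value as undefined rather than aborting.  No
multiple-testing correction is applied across the 15 predictors at this
exploration stage.  One caveat found while verifying: a 3-vs-0 table on
n=770 (prolactin deficiency) yields p ≈ 4×10⁻⁴ by Pearson and ≈ 7×10⁻³
by Fisher, so a literal "OR > 5 and p < 10⁻⁴" screen retains 9 rather
than 10 variables; prolactin still reaches the model through the
anterior-deficiency count.

## Decision tree

`GainRatioTree` implements C4.5-style induction: nominal attributes
split multiway (one child per observed value), numeric attributes split
binary at midpoints between adjacent observed values, split quality is
the gain ratio (information gain divided by the intrinsic entropy of the
partition), every child must hold at least `min_records = 2` rows, and
no post-pruning is applied by default.  The Gini index and a classic
reduced-error pruning pass are available as options for robustness
checks.  Ties in gain ratio resolve deterministically: earliest feature
in column order, then lowest threshold; leaf majorities tie toward
`control` (the type-I-conservative label).  Refitting after a row
permutation yields an identical tree.

The anterior pituitary axes (TSH, ACTH, prolactin) enter the model as a
single ordinal feature `anterior_deficiency_count` capped at 2, read as
0 / 1 / ≥2 — "≥2" being the multiple-deficiency category that the final
rule's second clause uses.  A missing axis flag counts as not deficient
by default (`'missing'` policy available).

Missing split values: rows with a missing attribute are excluded from
that split's evaluation and routed to the largest child at prediction
time; fractional-instance C4.5 weighting is out of scope.  The gain is
*not* scaled by the known-value fraction by default.  The scaling
penalty (a C4.5 convention, available via `missing_gain_scaling=True`)
multiplies the gain of an attribute observed in only 28% of patients by
0.28, which demotes pituitary dysgenesis — a perfectly case-pure finding
wherever it is observed — below weak fully-observed predictors.  The
clinical modelling intent is the opposite: an MRI finding should compete
on the strength of its assessed subset.  With the default, the fitted
tree places the anterior-deficiency count at the root and pituitary
dysgenesis immediately below it, and both head the ensemble relevance
ranking.  Node class-count conservation (parent = sum of children) holds
exactly on complete data and is tested there; under missingness the
excluded rows are intentionally not propagated.

False-positive branch pruning: after fitting, the subtree through which
the most false positives flow is collapsed into a control-labelled leaf.
Ties resolve to the deepest such subtree (same false positives removed at
the least cost in sensitivity), then to preorder position.  The
operation's contract is directional — specificity never decreases,
sensitivity never increases; a single prune removes all false positives
only when one branch contains them all.  A repeated stratified 80/20
holdout harness (`cross_validate_tree`) reports metric dispersion across
repeats.

## Feature relevance ensemble

`TreeEnsembleRelevance` grows 100 gain-ratio trees on bootstrap
resamples, considering a random ⌈√p⌉-feature subset at every split
(both defaults chosen as the conventional tree-ensemble settings; the
original analysis names only the ensemble method, not its parameters).
Relevance is the number of splits on each feature weighted by
1/(1+depth), with level-0/1/2 split counts reported separately.  The
ensemble is used only for ranking robustness, never for prediction, and
is deterministic given its seed.

## The clinical rule

The rule is a fixed, interpretable classifier with three clauses —
dysgenesis; ≥ 2 anterior deficiencies; exactly 1 anterior deficiency
plus a qualifying comorbidity (neonatal hypoglycemia, neonatal
hypogenitalism, central diabetes insipidus, midline abnormality,
(supra)sellar tumor/surgery, cranial radiotherapy ≥ 18 Gy).  Decisions
carry a trace (which clause fired, which comorbidities qualified,
whether missingness was encountered).  Missing flags never satisfy a
clause.  The rule refuses ineligible patients: it is validated only for
children meeting the GHRS testing criteria.  Two properties are enforced
by randomized sweeps in the tests: monotonicity (flipping any predictor
false→true never turns a positive decision negative) and
missing-robustness (replacing false with missing never turns a negative
decision positive).

## Evaluation

All metrics derive from the confusion matrix; any metric whose
denominator is zero is reported as undefined, never as 0.  Proportions
carry Wilson score intervals — the method that remains well-behaved at
the proportions near 0 and 1 this regime produces, and the one that
reproduces the reference intervals used in the tests.  LR+ is
sens/(1−spec), rendered ">1,000" at perfect specificity with ∞ retained
internally.  NNT (number needed to test/diagnose) is 1/(PPV+NPV−1); this
formula is verified in the tests as the unique simple candidate
reproducing all three reference values (1.14, 1.19, 1.21) from their
confusion matrices.  The NNT interval propagates the Wilson bounds of
PPV and NPV, a conservative choice.

Validation applies three axes: safety (false-positive rate ≤ 1%, since a
single false positive in 125 controls is accepted as "type I error near
zero"), usefulness (sensitivity > 0.2), and significance — an exact
upper-tail binomial test of the correct-positive count among all
rule-positive calls against the cohort's pre-test GHD probability,
judged at α = 10⁻⁵.  The random variable behind the significance test is
one defensible reading of a loosely specified procedure and is exposed
as an explicit function of (correct positives, total positives, prior).
ROC analysis is out of scope: the predictors are binary.

## Synthetic cohorts

No patient-level data are deposited for studies of this design, so the
generator is a first-class module.  `exact_marginal` mode lays out flag
assignments deterministically so that every predictor's case/control
2×2 table equals its integer target, MRI availability is differential by
status (120/150 cases, 98/620 controls in the derivation spec), the
isolated/multiple-deficiency split matches (86/64 and 20/16), and the
clinical rule applied to the output reproduces the target confusion
counts (61 TP / 0 FP derivation; 20 TP / 1 FP validation).  The layout
follows clinical archetypes: dysgenesis cases absorb the surplus axis
deficiencies (congenital multiple-deficiency patients), rule-positive
deficiency carriers come next (pairs of deficiencies, then single
deficiencies each paired with a qualifying comorbidity), acquired-
condition flags (tumor, radiotherapy, chemotherapy) concentrate in the
remaining cases.  Infeasible integer targets raise an error naming the
conflicting margins.  The joint distribution of predictors is
under-determined by the marginal tables; only marginal fidelity, the
deficiency-structure counts and rule-consistency are claimed.

The validation cohort's per-predictor counts are not published; the
built-in validation spec uses package-chosen plausible constants
consistent with the published confusion counts and deficiency split.
The reading TP=20/FP=1 follows the validation sensitivity (55.6% of 36)
and the single described false positive; the alternative "21 predicted"
figure appearing in the cohort-characteristics table is internally
inconsistent with those and is not used.  Likewise the derivation
cohort-characteristics table's predicted/not-predicted deficiency split
(18+82 isolated) contradicts its own total (86); the generator targets
the total.

`stochastic` mode draws each patient independently: case status is
Bernoulli(150/770), case flags are Bernoulli draws conditioned on one of
four clinical archetypes (congenital multiple-deficiency 0.40,
idiopathic isolated 0.45, acquired 0.10, neonatal-onset 0.05 — weights
chosen so the congenital block roughly matches the observed
multiple-deficiency fraction).  Per-archetype rates are calibrated by
bisection so the mixture-averaged rate equals the spec's conditional
rate for every predictor exactly; empirical rates are tested to stay
within Monte-Carlo error at n = 10,000.

Auxology (age, height/weight/BMI SDS, IGF1 SDS) is sampled per status
from normals matching the reported medians with σ = IQR/1.349; tails are
unconstrained because only medians and IQRs are reported.  Ages clip to
[0.1, 17.9] years.  GH peaks are placeholders with correct ascertainment
behaviour, not a physiologic model: uniform below 95% of the era cut-off
for cases, with at least one arm at or above it for controls.  Weight is
a coarse affine function of age and weight SDS, used only to trigger the
one-arm-under-10 kg convention.  Every generated child satisfies a GHRS
criterion (a growth-deceleration value is imposed when the sampled
auxology would not qualify), so the rule's eligibility precondition
holds by construction.  Cohorts are shuffled after construction so row
order carries no status signal, and a fixed seed gives a byte-identical
CSV.

What passing tests on these cohorts do and do not show: they demonstrate
that the pipeline's statistics, tree machinery and rule reproduce the
reference contingency structure exactly and behave correctly under the
stated missingness and correlation patterns; they do not validate the
rule on real patients, and the decision tree's full confusion matrix is
not expected to match the reference tree's (74/5) because the
patient-level joint distribution is unknowable from marginal tables —
only the direction of the pruning shift is asserted.

## Problem sizes and determinism

All computations run at the study's own scale (770 and 161 patients;
10,000 for stochastic calibration checks; 100-tree ensembles), which
keeps the full test suite under a minute on one CPU.  Every stochastic
component takes an explicit seed; the exact-marginal layouts and the
reported headline quantities are seed-invariant by construction.
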