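# Methods

This note documents the statistical procedures implemented in `pascdx`,
the modelling assumptions behind the synthetic data, the numerical
choices, and the limits of what the test suite demonstrates.

## The diagnostic chain

The pipeline converts case/control metabolite abundances into a
disease-level call in four stages.

**Screening.** Each metabolite is tested with a two-tailed two-sample
t-test assuming unequal variances (Welch). The statistic is
t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite degrees of
freedom; abundances are log-transformed by default before testing,
since metabolomics intensities are right-skewed and the t-test holds
its nominal level much better on the log scale at moderate n. Selection
is at raw p ≤ 0.05 with **no multiplicity correction**: the screen is a
recall-oriented candidate filter feeding a classifier, not an
inferential endpoint, and false positives are diluted rather than
propagated. Benjamini–Hochberg FDR control is available behind a flag
for users who want a conservative screen. Degenerate inputs follow the
limit of the statistic: both variances zero with equal means gives
p = 1, with unequal means p = 0 (flagged); missing values are dropped
per metabolite, with fewer than two finite values per group reported as
insufficient data.

**Negative controls.** The classifier's negative class is drawn
uniformly without replacement from a reference metabolite library,
excluding every screened-positive id (string match on metabolite id; a
structure-level duplicate check is out of scope because the synthetic
library carries no redundant structures). Class balance is exact by
construction. The sensitivity of downstream accuracy to this random
draw is quantified by a stability check: one stratified 90/10 split,
then 100 refits of a random-forest reference model on resampled-with-
replacement training negatives, reporting the SD of held-out accuracy.

**Descriptor selection.** Metabolites are represented by numeric
molecular descriptors (any externally computed table with the package's
CSV schema; an RDKit-based stand-in generator is included). Cleaning
drops columns with >10% missing cells, median-imputes the rest, and
drops zero-variance columns, logging every action. Subsets are scored
by the CFS merit k·r̄_cf / √(k + k(k−1)·r̄_ff). Correlations are Pearson
on the continuous descriptors with the class encoded 0/1
(point-biserial), in absolute value; a symmetric-uncertainty variant
(equal-frequency 10-bin discretization) is available for sensitivity
analysis, since entropy-based CFS variants exist and the choice is
genuinely open. The search is forward best-first: expand the
highest-merit open subset by every unused feature, stop after 5
consecutive expansions that fail to improve the best merit seen, return
the best subset encountered. Ties break toward the lexicographically
smallest index tuple, making the search deterministic and
permutation-equivariant. One degeneracy rule: a candidate feature
perfectly correlated (|r| ≥ 1 − 1e−12) with a current subset member is
never added beside it — a perfect correlate carries no additional
information, and without this rule the merit formula can *prefer*
adding an exact duplicate of a strong feature (it raises r̄_cf faster
than the redundancy term grows). The exhaustive oracle used in testing
enumerates the same duplicate-free subset family, so heuristic and
oracle optimize the same objective.

**Modelling.** Five families (MLP, RF, LR, RBF-SVM, GB) run inside a
pipeline that z-scores descriptors on training data only. Default grids
(all overridable): MLP hidden sizes {(32,), (64,), (64,32)} × L2
{1e−4, 1e−2}; RF trees {200, 500} × depth {∞, 10}; LR C {0.01, 0.1, 1,
10}; SVM C {0.1, 1, 10} with scale gamma (probabilities via
cross-validated calibration of the decision values); GB {100, 300}
learners × learning rate {0.05, 0.1}. Performance is AUC-ROC —
implemented from the Mann–Whitney definition (midranks; tied
positive/negative pairs count ½) so that it is exactly the probability
a random positive outscores a random negative and exactly the
trapezoidal area under the ROC curve. Repeated stratified 5-fold CV
(10 repeats) yields 50 fold AUCs; the summary interval is their
empirical middle 95% (2.5th–97.5th percentiles). Grid search runs
nested inside the training folds of each outer split, so hyperparameter
choice never sees held-out data; a canary test with a
partially-label-encoding column verifies the absence of leakage. The
per-metabolite decision threshold on the probability score is 0.5;
the disease-level threshold (below) operates on the set statistic, not
the score.

**Set-level diagnosis.** For a disease's dysregulated set, the
proportion-classified statistic is the mean of the per-metabolite
flags. The bootstrap resamples the *metabolite flags* with replacement
at the original set size, 500 replicates, percentile CI — metabolites
are the unit the classifier sees, so they are the resampling unit. The
decision threshold between a reference and its most confusable
comparator is found by lowering the interval confidence level from 0.95
in steps of 0.001 (resolving three decimals) and stopping at the first
level where the comparator's upper endpoint falls strictly below the
reference's lower endpoint; the threshold is the midpoint of the gap,
with both endpoints reported, and the result is marked non-separable if
the reference median does not exceed the comparator's or no level
separates them. Cross-disease matrices train one model per disease with
a shared spec and pipeline and report, per cell, the proportion of the
column disease's positives flagged by the row disease's model, with a
plain (uncorrected) Wilson score interval at 95%.

## The synthetic study

The generator produces the structure the chain assumes, with ground
truth always returned beside the data:

* **Abundances** are log-normal: per-metabolite baseline log-means ~
  N(10, 2²) (intensities spanning a few orders of magnitude), unit
  within-group SD on the log scale. The planted dysregulated
  metabolites have their case-group log-mean shifted by `effect_size`
  SD with a random sign. Defaults: 50 cases, 50 controls, 500
  metabolites, 120 dysregulated at 1.5 SD — a mid-sized two-arm study
  in which the screen has high power without being trivial. The
  log-normal form is a modelling choice; it is not estimated from any
  particular assay.
* **Descriptors** are standard normal per column; the informative
  columns add `descriptor_shift` to disease-dysregulated metabolites.
  Defaults: 200 descriptors, 20 informative, 0.8 SD shift — a
  between-class Mahalanobis separation of ≈3.6, which puts trained
  classifiers in the high-0.9 AUC regime. An optional block
  equicorrelation (`block_rho`, default off) emulates descriptor
  collinearity; it is off by default so the analytic oracles used in
  testing stay exact.
* **Disease overlap.** Disease 0's signature is the first
  `n_informative` columns; each further disease shares
  `round(overlap · n_informative)` of them and takes the rest from
  fresh columns. `overlap = 1` makes two diseases' descriptor
  distributions identical (the mutually-confusable case); `overlap = 0`
  makes them disjoint.

What the synthetic data does *not* emulate: real metabolome covariance,
assay-specific artifacts, descriptor distributions of real
cheminformatics software (heavy tails, discreteness, massive
collinearity), or cohort confounders such as age. Passing tests
therefore demonstrate that the chain's statistics behave as designed
under its stated assumptions — calibrated screen, correct search,
calibrated bootstrap, correct threshold rule, recovery of planted
overlap structure — not that any particular clinical performance level
would be attained on patient data.

## Numerical and design choices

* **Seeds.** Every stage derives its RNG stream from
  `SeedSequence([global_seed, crc32(stage_name)])`, so one global seed
  reproduces a run byte-for-byte and unrelated stages cannot perturb
  each other's draws.
* **Welch zero-variance convention** and **Wilson boundary cases**
  (k = 0 → low exactly 0, k = n → high exactly 1) are handled exactly
  rather than through floating-point limits.
* **Interval percentiles** use linear interpolation (the numpy
  default) everywhere — bootstrap CIs, the middle-95% CV interval and
  the confidence scan — so the scan and its oracle agree to the step
  size.
* **Threshold = gap midpoint.** The first-disjointness gap has two
  endpoints; the midpoint is symmetric between reference and
  comparator, and both endpoints are reported for users who prefer a
  conservative choice.
* **Problem sizes in tests and the acceptance script** use the default
  signal structure at reduced metabolite/descriptor counts (300
  metabolites, 60 descriptors, 120-metabolite disease sets) — the
  package's chosen mid-size study — with the single-configuration MLP
  carried end to end.

## Known limitations

* CFS correlations are Pearson; strongly non-monotone
  descriptor–class relationships would be under-weighted (the
  symmetric-uncertainty variant mitigates this at the cost of
  discretization).
* Best-first search is a heuristic; its near-optimality is verified
  exhaustively only up to 12 descriptors.
* The confidence-shrinking threshold rule conditions on the observed
  bootstrap clouds; it quantifies separation of these samples, not a
  generalization guarantee for future cohorts.
* Feature selection is performed once on the full training table
  before cross-validation (the selected descriptors are treated as the
  metabolite representation); CV intervals therefore do not account
  for selection variability.
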