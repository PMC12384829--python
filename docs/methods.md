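# Methods

This note documents the statistical procedures implemented in `pdcognet`,
their assumptions, the tunable parameters and their defaults, and the design
choices made where several conventions were defensible.

## Outcome definition and transition classes

Cognitive status is the MoCA total binarized at the standard cut-off:
**Intact** iff MoCA ≥ 26 (ties at 26 are Intact), **Impaired** otherwise.
Baseline and 3-year follow-up labels jointly assign one of four transition
classes — Cognitively Intact (Intact→Intact), Stable Impaired
(Impaired→Impaired), Conversion to Impaired (Intact→Impaired), Reversion to
Cognitively Intact (Impaired→Intact). The transition classes never enter
training; they are used descriptively and for the per-class error table.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis relies on,
not the marginal distributions of any named instrument.

**Structure.** 20 variable groups totalling 166 columns, with the per-group
variable counts of the original instrument blocks. The published block table
lists 21 rows while the masking analyses enumerate 20 groups; this package
merges the two single binary treatment flags (PD-medication use, deep-brain
stimulation) into one 2-variable `TREATMENT` group so both constraints hold.

**Correlation model.** One unit-variance latent factor per group. Each
observed variable is `ρ·f_g + σ·ε` with loading ρ = 0.8 (per-group
`block_correlation`) and noise σ = 0.6, giving within-group correlations of
ρ²/(ρ²+σ²) = 0.64 and between-group population correlations of 0. One
dominant factor per block guarantees that the λ ≥ 1.5 retention rule keeps at
least one component in every PCA-eligible group, as in the source analysis.
The single-factor model is deliberately simpler than real data: real
instrument blocks have several correlated sub-factors (the original analysis
retained up to 5 components for the motor exam), and real between-group
correlations are not exactly zero. Passing tests therefore demonstrate
correctness of the machinery under the assumed block structure, not
performance on PPMI data.

**Outcome model.** Follow-up impairment is Bernoulli with
`logit = b0 + Σ_g β_g f_g`. Four groups are informative by default, mirroring
the groups all three published explainability methods agreed on, with
log-odds effects chosen to mirror their reported importance ordering:
STAI 1.2, MoCA 1.1, MDS-UPDRS III 0.9, HVLT-R 0.8. The intercept `b0` is
solved by Brent root-finding so the expected prevalence matches the target
192/618 ≈ 0.311 exactly (the realized Bernoulli draw varies by binomial
noise, SE ≈ 0.019 at n = 618). An unbracketable intercept raises an
"infeasible spec" error.

**MoCA scores.** The baseline MoCA column doubles as the baseline
predictor: an integer score derived from the MoCA group's factor by
`round(26.9 − 2.2·f)` (approximating the published baseline mean 26.92 and
SD 2.51), with the rounding boundary placed at the empirical factor quantile
so the binarized baseline prevalence matches its target 147/618 within
rounding ties. Follow-up MoCA is an integer score from the standardized
outcome logit, clamped to the side of the cut-off its sampled label demands.
Any consistent latent→integer mapping would do — only the binary labels feed
the pipeline. Because baseline and follow-up labels share the MoCA factor,
all four transition classes are populated at the default conditions.

**Missingness.** Strictly MCAR: each predictor cell is masked independently
with probability `missing_rate` (< 0.20, the admissibility threshold for a
variable). The MoCA column is never masked, since the outcome-defining
instrument is complete by construction of the inclusion criteria. The real
missingness mechanism is uncharacterized; MCAR is the neutral default.

**Determinism.** Everything derives from `CohortSpec.seed` via
`numpy.random.default_rng`; identical specs give bit-identical cohorts.

## Preprocessing

* **Imputation**: round-robin iterative imputation with an
  extremely-randomized-trees regressor per column (scikit-learn
  `IterativeImputer` + `ExtraTreesRegressor`), `max_features="sqrt"` per
  split as random-forest imputers conventionally use, 10 trees and at most
  10 rounds (tolerance 1e-3) by default — a speed-oriented setting; the
  classic 100-tree ensemble is one config field away. A `mean` mode exists
  as a fast fallback. Observed cells are never modified; a column with ≥ 20%
  missing or entirely missing raises. Seeded and deterministic.
* **Standardization**: per-column z-scores with population SD (ddof = 0),
  scikit-learn `StandardScaler` semantics; fitted parameters are stored for
  reuse on new data. Constant columns standardize to all-zeros
  (divide-by-zero guard) and are logged.
* **Group-wise PCA**: applied to groups with ≥ 6 variables ("more than 5"),
  eigen-decomposition of the group's sample correlation matrix (the
  Kaiser-style rule presumes unit-variance inputs). Components with
  eigenvalue ≥ 1.5 are retained; ties at exactly 1.5 are retained (measure
  zero in practice). If no eigenvalue reaches 1.5 the first component is
  retained anyway — every published PCA'd group kept ≥ 1 component, and
  silently dropping a block would change the feature space. Component signs
  are fixed by making each component's largest-|loading| entry positive.
  Scaling and PCA are fitted on the full dataset before cross-validation,
  mirroring the described order of the source analysis; note this leaks
  distributional information across folds — refitting per fold would be the
  leak-free variant and can be assembled from the same primitives.

On the default synthetic cohort the 166 columns reduce to 21 (10 blocks of
size ≥ 6 → 1 component each, plus 11 pass-through columns); the original
analysis reported 166 → 28 because several real blocks carry more than one
strong component.

## Classifier and training

Architecture: input → hidden layers (default one layer of 7 units, leaky
ReLU, negative slope 0.01 — the slope is unspecified upstream and
configurable here) → 2-unit softmax in fixed (Intact, Impaired) order.
Initialization is symmetric scaled-uniform (Glorot) with zero biases,
seeded.

Loss: focal cross-entropy `−α_t (1−p_t)^γ log p_t` averaged over the batch,
with α = (0.5, 2.0) and γ = 1.5; p_t is clipped to [1e-7, 1−1e-7] against
log(0). At γ = 0, α = (1,1) the loss and its gradient reduce exactly to
softmax cross-entropy (tested). Gradients are exact analytic
backpropagation; the derivative of leaky ReLU at 0 is taken as 1.

Optimization: mini-batch Adam (step 1e-3, decays 0.9/0.999, ε 1e-8 — the
standard published constants), batch size 8, at most 50 epochs, per-epoch
shuffling with a per-epoch child seed, last partial batch kept. A stratified
10% validation split (at least one subject per class) is carved from the
training partition; early stopping monitors validation loss with patience 5
and restores the best-epoch weights. Patience and split size are
package conventions, not upstream values.

Prediction: Impaired iff P(Impaired) ≥ τ with τ = 0.5; ties at the threshold
go to Impaired.

Architecture search: a 3 × 3 grid over depth {1,2,3} and width {7,9,14},
compared by pooled cross-validated Impaired recall, then fewest Intact-class
errors, then fewest parameters.

## Evaluation

5-fold stratified cross-validation (scikit-learn `StratifiedKFold`,
shuffled, seeded); per-fold class counts deviate from proportionality by at
most one subject. Each fold model is scored on its held-out fold; the model
with the highest held-out Impaired recall is selected (ties: fewer Intact
errors, then lowest fold index). The selected model is then evaluated on
the **entire dataset**, as the source analysis did; this is optimistically
biased and all reports label it as in-sample, with the pooled held-out
confusion aggregate emitted alongside.

Metrics: recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = harmonic mean,
micro accuracy, and per-class values by swapping the positive class. The
"overall" row of the published table mixes conventions; this package reports
micro accuracy and macro recall (unweighted mean of the two class recalls)
explicitly and does not attempt to reproduce a blended overall F1. Undefined
ratios (zero denominators) are reported as `None`, never as 0. Display
rounding is half-up to 2 decimals; raw values are retained in JSON.

ROC: thresholds are the sorted unique predicted probabilities (prepended by
+∞ so the curve starts at (0,0)); AUC by trapezoidal integration, which
equals the Mann-Whitney rank statistic with ties counted half (tested
against a brute-force pair-count oracle and scikit-learn).

## Explainability

All three methods share one value-function convention: masked features are
replaced by **zeros**, i.e. the per-feature means after standardization,
making the Shapley game and the masking procedures commensurable. The
attribution target is the predicted probability of the Impaired class (not
the logit). Explanations are computed with the selected best model on the
full dataset, matching the final-evaluation object.

* **Exact Shapley** (≤ 15 features): full subset enumeration of
  v(S) = P(Impaired | features outside S at background), with the standard
  combinatorial weights. Satisfies efficiency (Σφ = v(full) − v(empty)),
  symmetry and the dummy axiom to numerical precision (tested).
* **Sampled Shapley**: Monte-Carlo average of marginal contributions over
  random feature orderings (default 200 permutations per subject, seeded per
  subject); an unbiased estimator of the exact values, with error shrinking
  as 1/√n_permutations. 2000 permutations agree with enumeration to < 0.01
  on a 10-feature model (tested). Global importance is the per-feature mean
  |φ| across subjects; for group-level comparison, mean-|φ| is **summed**
  over a group's columns (the upstream aggregation is unstated; summation is
  this package's documented convention).
* **Group masking**: ΔRecall = recall(group zeroed) − recall(unmasked), no
  retraining, input dimensionality preserved. Large negative ΔRecall =
  important group.
* **Combinatorial masking**: every subset S of groups with 1 ≤ |S| ≤ 5,
  enumerated lexicographically in group-map order (deterministic, streaming),
  recall recomputed per subset, report sorted ascending by recall with
  lexicographic tie-breaks. For 20 groups this is Σ_{k=1..5} C(20,k) =
  **21,699** subsets. (A printed figure of 21,700 circulates for this
  quantity; it equals the count including the empty set. The enumeration
  here follows the stated bounds 1 ≤ |S| ≤ 5.)

## Pipeline determinism and problem sizes

A single master seed fans out to per-stage child seeds by hashing the stage
name (`_seeds.child_seed`), so stages can be re-run in isolation and full
reruns produce byte-identical reports (wall-times live only in the run
manifest). All outputs are plain CSV/JSON.

Default problem sizes are the study conditions themselves: 618 subjects,
166 variables, 5 folds, 200 Shapley permutations, subset sizes ≤ 5. The
test suite exercises the full 618-subject cohort for training, attribution
and enumeration; the end-to-end double-run determinism test uses a 250-subject
cohort with mean imputation and 25 permutations, a scaled configuration
chosen so the repeated full-pipeline runs stay cheap while exercising every
stage.

## Known limitations

* The generator's single-factor blocks cannot reproduce multi-component
  retention patterns (e.g. 5 motor-exam components) or realistic instrument
  marginals (binary genetic flags are modeled as continuous block members).
* Full-dataset evaluation of a CV-selected model is optimistically biased by
  design fidelity; use the pooled held-out aggregate for honest error rates.
* Standardization/PCA fitted before CV leaks across folds (kept for
  fidelity; a per-fold mode is straightforward with the same primitives).
* The focal-loss probability clip makes the loss locally constant in p_t at
  the clip boundary; gradients there are defined as 0.
* Shapley sampling cost grows as subjects × permutations × features; the
  implementation batches all evaluations per subject but is still the
  slowest stage at default sizes.
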