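# Methods

## Data model

A haplotype table holds one profile per male sample: an allele call per
locus-copy of a marker panel. Alleles are canonicalized strings ("14",
"13.2") and compared only as categories; the numeric value is used
solely for deterministic ordering (exact `Fraction` comparison, so
13 < 13.2 < 14 with no float artifacts). Multi-copy markers (DYS385ab)
are stored as two locus-copies in nondecreasing numeric order, the
convention genotyping reports use. A missing call is a `None` sentinel,
distinct from allele "0"; readers map empty cells and common NA tokens
to it. DYS389II is stored as reported, with no subtraction of the
DYS389I fragment. The default panel follows the printed 20-locus
forensic screening set verbatim (18 locus names, 19 locus-copy columns
after the DYS385a/b split); any other panel can be supplied as JSON.

## Preprocessing

Profiles with any missing call are excluded outright (no imputation).
Population labels map to integers in lexicographic order. The
stratified 80:20 split apportions per-class train counts by the
largest-remainder rule (round-half-up globally, remainders to the
largest fractional parts, name-order tie-break), so it is deterministic
and proportional within one sample per class. Class balancing
downsamples every class, without replacement, to the smallest class
size — applied to the **training partition only**, after the split, so
the test partition keeps natural class proportions and support-weighted
test metrics remain meaningful. Applied to the published reference
class sizes (839/333/273/520/220/443/960) the rule yields 220 per
class. The split-then-balance order is one consistent reading of the
source procedure; both stages are independently callable if the other
order is wanted.

## Feature encoding

The vocabulary is the union of observed (locus-copy, allele) pairs in
deterministic order (panel order, then numeric allele order); one-hot
encoding yields a binary matrix whose rows, for complete profiles, sum
to the panel's locus-copy count. In the end-to-end pipeline the
vocabulary is fixed on the complete table *before* splitting
(encode-then-split), so held-out profiles never carry out-of-vocabulary
alleles; when a model is applied to genuinely external data, unseen
alleles raise by default (they silently change row sums otherwise), and
an explicit permissive mode encodes the locus as all-zeros with a
warning for screening use.

Mutual information between a binary feature and the labels is the
plug-in estimate in nats with 0·log 0 := 0 and no bias correction —
adequate for its exploratory, ranking-only role. The optional
one-feature-per-marker selector keeps, per locus-copy, the feature with
maximal MI (ties to the lowest numeric allele), reducing a k-class
problem to one feature per locus-copy; the default pipeline uses the
full one-hot matrix, and the selector exists for sensitivity analysis.

## Experts, calibration, attention, meta-network

Each population gets a binary expert (population vs rest). Supported
families: L2 logistic regression, random forest, XGBoost; all
single-threaded and seeded. When no spec is given, hyperparameters are
chosen by a sequential model-based optimizer: a Matérn-5/2 Gaussian
process fit to evaluated points on the unit cube, next point by
expected improvement over a random candidate pool, objective = mean
stratified k-fold balanced accuracy (appropriate for the ~1:(k−1)
imbalance OvR creates). The warm-up is space-filling random; the whole
loop is reproducible from one seed.

Calibration follows Platt: P(y=1|s) = 1/(1+exp(A·s+B)), (A, B) by
maximum likelihood with Platt's smoothed targets ((N₊+1)/(N₊+2),
1/(N₋+2)), which keep the parameters finite on separable data. The fit
uses **out-of-fold** scores from a stratified k-fold loop (default 3
folds), so the sigmoid corrects genuine generalization overconfidence
rather than resubstitution artifacts. A CV diagnostic reports held-out
NLL before/after calibration. A well-oriented expert yields A < 0.

Attention weights are softmax((balanced_accuracy + MI)/T) across
experts, with T = 1 by default: the two ingredients the method
prescribes (validation performance and mutual information), made
commensurable by normalizing the MI term — the maximum single-feature
MI against the expert's binary target divided by that target's entropy,
so both summands live in [0, 1]. The fused representation passed to the
meta-network is the k weighted terms wᵢ·pᵢ **plus their sum**: this
preserves both readings of the aggregation rule (the scalar weighted
sum, and the structured per-classifier output) at the cost of one
redundant column. The complementary negative-class probabilities are
omitted as exact complements.

The meta-network is a fully-connected classifier (ReLU hidden layers,
softmax output, cross-entropy loss, Adam) via scikit-learn's
`MLPClassifier`; default two hidden layers (64, 32), 300 epochs,
learning rate 1e-3, fixed seed, all config-overridable. Early stopping
is disabled so a run always consumes its configured epoch budget and is
bit-reproducible. Note the budget interacts with the learning rate: the
experiment designs below use (32, 16) × 200 epochs at 1e-2, which
converges reliably on their low-dimensional fused features. The
meta-network is trained on out-of-fold fused probabilities (stacking
discipline), never on resubstitution outputs. Argmax ties break to the
lowest class index.

## One-vs-one comparator

One calibrated binary classifier per unordered pair, trained only on
its two classes' samples; k(k−1)/2 in total. The stacking combiner uses
the same meta-network design over the vector of calibrated pairwise
probabilities (probabilities, not votes — votes discard confidence).
The pairwise-accuracy matrix scores each pair's classifier on held-out
samples of its two classes only; it is symmetric by construction, with
NaN on the diagonal and for pairs absent from the test set (serialized
as null). Both architectures are evaluated by the same module on the
identical split, so comparisons are apples-to-apples.

## Evaluation surfaces

Confusion matrices (rows true, columns predicted), per-class
precision/recall/F1 with support-weighted and macro aggregates
(weighted recall ≡ accuracy, asserted to 1e-12), a misclassification
summary (off-diagonal cells by count, name-order tie-break), per-population
discriminative-feature rankings (tree impurity importances, or
|coefficient|×feature-SD for linear experts, normalized to max 1 — the
0–1 scale is an interpretation, chosen because the reference scores are
reported on such a scale without definition), and expected calibration
error over equal-width bins.

## Simulator

Each population is a set of independent per-locus-copy categorical
allele distributions drawn from a symmetric Dirichlet; allele labels
come from a realistic repeat range (default 8–20) with a configurable
microvariant probability (default 0.1). Admixture between populations
is frequency-vector mixing (alpha·a + (1−alpha)·b); missingness is MCAR
(the pipeline filters missing profiles outright, so the mechanism is
irrelevant downstream). Deliberately **not** modeled: linkage between
loci (the classifiers never use inter-locus dependence, and
independence keeps the oracles analytic), coalescent/mutation realism,
haplogroup structure. Passing tests therefore certify the machinery —
encoding, calibration, fusion, stacking, ranking — under the
distributional assumptions the method itself makes, not performance on
real forensic databases, where linkage, database heterogeneity and
binning artifacts matter.

## Experiment designs and problem sizes

The canned experiments use logistic-regression experts and the
(32, 16)/200-epoch meta-network; sizes were chosen to make each effect
measurable while keeping replicate loops cheap.

* **Separable ceiling**: 7 populations with disjoint allele supports on
  the default panel, 220 samples each; both architectures should be at
  ceiling (≥ 0.95 observed as 1.0).
* **Null floor**: 7 identically distributed populations, 220 each;
  accuracy should match 1/7 within 3 binomial standard errors of the
  test size (308).
* **Admixture echo**: 3 populations on a reduced 9-locus panel
  (10 locus-copies, Dirichlet concentration 1.5, 6 alleles per locus,
  300 samples each), with POP2's model blended 0.6 toward POP1's. The
  reduced panel matters: on the full 19-copy panel the remaining loci
  carry so much signal that the blended pair stops producing test
  errors at these sample sizes and the effect becomes unmeasurable.
  Across 20 seeded replicates the blended pair should be the minimum
  off-diagonal of the pairwise-accuracy matrix and host the largest
  misclassification cell of both architectures (≥ 90% of replicates).
* **Planted allele**: 3 populations sharing a base model except one
  carries a private allele at frequency 0.8 at a single locus (absent
  elsewhere — "most members carry it" rather than fixation); a
  random-forest expert's importance ranking should put that feature
  first in ≥ 95% of 20 replicates at 220 samples per class.

## Known limitations

* The simulator's independence assumption means real-data performance
  claims cannot be derived from these tests.
* The attention formula is one monotone, normalized instantiation of
  "performance plus mutual information"; the source describes the
  ingredients but not the arithmetic, so the exact weighting is a
  design choice (logged per run, temperature-adjustable).
* The OvO stacking combiner's form is likewise unspecified at the
  source; the symmetric choice (same design as the OvR meta-network) is
  an assumption recorded in the run manifest.
* Model directories persist auditable parameters (panel, vocabulary,
  calibration, attention, seeds) as JSON but fall back to joblib for
  the fitted tree ensembles, which have no portable JSON form.
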