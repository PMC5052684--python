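# Methods

This note documents the models behind each component, the defaults and
why they were chosen, the numerical decisions that matter, and the known
limitations — in particular what passing the synthetic-data tests does
and does not establish about real repository data.

## Differential expression: the Characteristic Direction

A two-class contrast (control vs perturbation, log2-scale expression,
genes × samples) is summarized by the unit normal of a regularized
linear-discriminant hyperplane. The computation (`diffexp`):

1. δ = rowmean(treatment) − rowmean(control);
2. SVD of the pooled, column-centered sample matrix; the first k
   components reaching `subspace_frac` cumulative variance are kept,
   k ≤ n₁+n₂−1 (truncation happens at the first component meeting the
   threshold);
3. in component space, the pooled within-class scatter Σ̂ (denominator
   n₁+n₂−2) is shrunk toward a scaled identity:
   Σ_γ = γ Σ̂ + (1−γ)(tr Σ̂/k) I;
4. Σ_γ v = δ_projected is solved and the solution mapped back to gene
   space and L2-normalized. Positive coefficients mean higher in
   treatment; swapping the classes negates the vector exactly.

Defaults: `gamma=0.5` (equal weight to data and identity — the scatter
of a handful of replicates is noisy), `subspace_frac=0.95` (drops only
numerically negligible directions), `top_n=500` genes per direction when
discrete sets are cut (a typical served signature size; configurable).
For γ=0 the direction collapses to the mean difference; the test suite
exploits this, and checks the subspace shortcut against a dense
full-gene-space solve on 5-gene instances where the sample span covers
the whole space.

Welch's t is oriented like CD and fold change (positive = up in
treatment) so that all three methods rank genes on the same sign
convention; genes with zero variance in both classes get t = 0 with a
warning rather than an undefined value.

`cut_signature` breaks ties lexicographically on the gene symbol, making
served sets reproducible across runs and platforms.

## Batch effects

Samples sharing a scan date are assumed to share a processing batch;
samples without a date form a single `unknown` batch (one batch, not one
per sample, to avoid exploding the design rank).

**Variance attribution (`pvca_lite`).** Principal components reaching
60% cumulative variance are scored: per PC, the R² of one-way group-mean
fits on batch and on condition; the explained part max(R²_b, R²_c) is
split between the two factors in proportion to their R² (shared variance
split proportionally) and the rest is residual; PC attributions are
averaged weighted by eigenvalue fraction and renormalized to sum to one.
This is an eigenvalue-weighted R² decomposition, not a mixed-model
variance-component fit: it preserves the quantity's meaning (how much of
the expression variance moves with batch vs condition) at a fraction of
the complexity.

**Surrogate variables (`estimate_surrogate_variables`).** Each gene is
residualized on the condition design. The number of surrogates is chosen
by comparing the singular-value variance *shares* of the residual against
a null built by permuting entries within each gene row (B=20
permutations, 95th percentile, components kept contiguously from the
top). Surrogates are then refined by 5 reweighting iterations: each
gene's weight is its strongest squared correlation with a current
surrogate, and the surrogates are recomputed from the weight-scaled
**original** (centered) matrix. Rebuilding from the original rather than
the residual matters: it lets a surrogate carry the condition-aligned
part of a partially confounded batch, which the removal step —
regression on [intercept, condition, surrogates] with only the surrogate
contribution subtracted — then attributes to the surrogate instead of
the condition. With residual-only surrogates (orthogonal to the
condition by construction), removal strips exactly the variance the CD
scatter was using to discount the batch direction while the aligned
contamination stays, and correction makes confounded contrasts *worse*;
we verified both behaviors on planted fixtures.

Known limitation: after a surrogate is removed, the residual is rank
deficient, which inflates every remaining component's variance share
above any within-row permutation null — so re-running the estimator on
corrected data reports spurious surrogates. The meaningful idempotence
property (the planted batch direction carries essentially no energy
after one pass) holds and is tested; literal "no significant surrogates
on a second pass" does not hold for this estimator family.

`correct_and_extract` requires ≥4 samples for surrogate estimation,
raises on a degenerate contrast before touching the data, and tags its
output `cd+sva`.

## Sanitization of crowdsourced submissions

Pipeline order: duplicate collapse (identical study + groups; earliest
kept) → integrity (all samples in the study, groups disjoint and
nonempty) → gene-symbol validation for gene perturbations
(case-insensitive canonicalization through the vocabulary's synonym
map) → swap detection → strict >10% curator rule. The first failing
filter decides a submission's removal reason.

Swap detection uses the perturbed gene's own expression: knockdown or
knockout with the target *up* by more than τ=1.0 log2 units in the
nominal perturbation group (or overexpression with the target down) is
called swapped and the groups are exchanged — corrected, not dropped.
Differences inside (−τ, τ) are undecidable: the submission is kept and
exported on a review queue, operationalizing a manual-review step that
cannot be automated. The curator invalid fraction counts invalid
verdicts plus swapped-as-submitted (the submission was wrong as
submitted even though it is repairable), evaluated before correction.

## Signed Jaccard similarity

sj(a, b) = [J(a.up, b.up) + J(a.down, b.down) − J(a.up, b.down) −
J(a.down, b.up)] / 2, with J(∅, ∅) := 0 so that scores stay bounded and
empty signatures have a defined self-score. The four-term sum is
computed with `math.fsum`, making symmetry and the exact negation under
up/down reversal hold to the last bit. Cluster ordering uses
average-linkage hierarchical clustering on 1 − score with a
canonicalized dendrogram (children ordered by the smallest id in their
subtree), so leaf order does not depend on input order. Tanimoto pairing
of structural fingerprints uses a strict `> threshold` rule (default
0.9); fingerprints are inputs, not computed here.

## Benchmarking

Scaled ranks order genes by |coefficient| descending with lexicographic
tie-breaks (a deterministic refinement of competition ranking), divided
by the total gene count; expected genes missing from a signature are
dropped and counted. ROC AUC is computed from midranks and equals the
Mann–Whitney probability with ties at ½; the reported staircase
integrates to the same value. DeLong's test uses the placement-value
covariance estimator (paired when the item sets coincide; independent
variance sums otherwise) with a two-sided normal p-value; identical
scores short-circuit to (z=0, p=1), and a zero variance with differing
AUCs raises rather than fabricating a p-value.
`benchmark_collection` pools per-gene (|coefficient|, gene ∈ expected
set) pairs across signatures per DEG method — pooling by concatenation,
with per-signature ROC available through the `roc` primitive directly.

## Text classifiers

Tokenization lowercases, splits on non-alphanumerics, drops single
characters and a fixed 50-word stop list, and Porter-stems purely
alphabetic tokens (alphanumeric tokens such as doses survive verbatim).
The stemmer implements the classic suffix-stripping rule tables and is
checked against published example stems. Lemmatization is deliberately
omitted: stemming dominates the vocabulary merge, and dropping the
lemmatizer removes a heavyweight dependency for a negligible vocabulary
difference.

Study categorization: per-field (title, summary, keywords) TF-IDF over
unigram+bigram stems — idf = ln((1+N)/(1+df)) + 1, document-wise L2
normalization — reduced by truncated SVD to the smallest k capturing at
least 10% of the squared-singular-value mass, concatenated across
fields, and fed to one of {gradient boosting, random forest, extra
trees, SVC} with a small declared grid searched by 3-fold stratified CV;
reported metrics (AUROC, AUPRC, MCC, F1) come from out-of-fold
predictions. Concatenation (rather than per-field ensembling) keeps one
model and lets the learner weigh fields; per-field models can be built
from the same primitives if needed.

Sample labeling: binary presence vectors over the token vocabulary of
the sample's metadata text; a bagging of 20 bootstrap-resampled
Bernoulli naive Bayes classifiers (Laplace α=1, presence *and* absence
likelihood terms); probabilities averaged and calibrated by isotonic
regression fitted on out-of-fold predictions from 10-fold stratified CV.
Calibrated outputs are therefore a monotone function of the raw bagged
scores, and with one estimator and no resampling the model reduces to
plain naive Bayes ("multinomial Bernoulli" in common usage is read as
the Bernoulli event model, which is what binary presence vectors
support).

## Automatic extraction

Thresholds (all configurable, defaults in `AutoExtractConfig`): study
category probability strictly > 0.9; cluster mean control-probability
> 0.7 → control group, < 0.3 → treatment group; clusters whose member
probabilities have population standard deviation > 0.2 discarded as
likely mixtures; DBSCAN with min_samples=2 on the Manhattan distance
between binary token vectors, eps = 3 token differences. At
min_samples=2 DBSCAN is exactly connected components of the
eps-neighborhood graph over non-isolated points; eps=3 reflects the
scale of the distance (counts of differing tokens): replicates of one
condition typically differ by a replicate token or two, conditions by
four or more. Singleton (noise) samples never form groups. Entity
labels come from an offline dictionary tagger (longest-match,
case-insensitive, word-boundary scan of the category's vocabulary with
synonym canonicalization before counting; most frequent term wins, ties
to the earliest mention), keeping the artifact self-contained rather
than depending on a web tagging service. Signature confidence is
operationalized as study-category probability × mean control probability
of the control group × (1 − mean control probability of the treatment
group), clipped to [0, 1].

## Synthetic data

`simulate_study` builds log2-scale matrices: per-gene baselines uniform
on [4, 12], Gaussian noise (sd 0.5 — a typical microarray log-scale
noise floor), planted DEG shifts of ±1.0 log2 units on treatment samples
(two within-class standard deviations; 50 genes of 1,000 by default),
and a rank-one scan-date batch shift (per-gene offsets, sd 0.5 by
default, i.e., comparable to the condition effect) whose alignment with
the condition is set by `batch_confound` (0 = crossed design, 1 = fully
confounded). For gene perturbations the perturbed symbol is guaranteed
measured, with a direction-consistent shift of twice the effect size so
that swap detection has signal. Sample titles come from small
category-specific grammars ("vehicle … rep n" vs "shTP53 knockdown …"),
study text embeds category keywords and mentions the entity twice plus a
decoy once (exercising the count-based tagger), and a heavier batch of
violations can be planted into submission pools per curator. All
randomness flows from a single seed; identical seeds reproduce corpora
byte-for-byte.

What the generator does *not* emulate: probe-level structure and
platform annotation, non-Gaussian heavy-tailed intensity noise (exposed
only through the test fixtures that add heteroscedastic scales),
correlated gene modules, multi-factor designs, free-text messiness of
real metadata (typos, multilingual text, inconsistent fields), and
corpus-scale class imbalance. Passing the planted-truth tests therefore
demonstrates the machinery is correct and well-calibrated under the
stated model, not that the classifiers' near-perfect synthetic AUROCs
transfer to real repository text, where reported performance is the
fixture-free question the benchmarks leave open.

## Problem sizes in the test suite

The suite favors many small, seeded instances: 5-gene oracle instances
for the dense CD check, 200-item ROC/DeLong fixtures (2,000-replicate
bootstrap), 30 random DBSCAN instances, 1,000-gene 5v5 studies for rank
recovery and batch correction (5 replicate studies for the
corrected-vs-uncorrected comparison), an 80-study training corpus and a
30-study evaluation corpus for the pipeline, and 88+12 submissions for
sanitization. These sizes keep the full run near twenty seconds while
leaving every statistical margin wide.
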