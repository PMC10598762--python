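# Methods

## Problem and model

`barcodeid` assigns species labels to fungal DNA barcodes (ITS sequences)
without alignment. A sequence of length L is reduced to its overlapping
k-mer counts (L−k+1 tokens, stride 1) against a vocabulary frozen on the
training corpus; classification is by gradient-boosted decision trees over
those counts. Boosting builds an additive ensemble ŷᵢ = Σₖ fₖ(xᵢ): each
round fits one tree per class to the gradient of the multiclass log-loss,
with complexity controlled by the leaf-count penalty γT and the engine's L2
leaf-weight penalty ½λ‖w‖². Tree induction (split finding, leaf-weight
solving) is delegated to XGBoost; this package owns the data contracts,
featurization, tuning loop, metrics and prediction plumbing.

The approach assumes within-species sequence divergence is much smaller
than between-species divergence, so that species share most of their k-mers
internally and differ externally — the standard barcoding premise. It is
alignment-free and orientation-sensitive: no reverse-complement
canonicalization is applied, so query sequences are expected in the same
orientation as the reference set (true of repository ITS data).

## Data contracts

* Species names are verbatim; provisional labels ("… sp.", "Uncultured …")
  are distinct classes. Label codes 0..S−1 come from a case-sensitive
  byte-order sort of the names, making the label map a pure function of the
  name set.
* Species with fewer than `min_count` sequences (default 7, configurable)
  are dropped before training; records sharing (species, exact sequence)
  are deduplicated on assembly, since mirrored repositories double-count
  barcodes.
* The TSV manifest is authoritative for species labels; a `species=` token
  in the FASTA description is the fallback, which lets self-describing
  FASTA round-trip without a manifest.

## Featurization choices

* Plain counts (not TF-IDF, not binary): the count of each vocabulary k-mer
  is the feature, the bag-of-words model applied to DNA.
* Vocabulary = sorted distinct k-mers of the training corpus only; at
  prediction time unseen k-mers are dropped (fit-then-transform contract).
  A query sharing no k-mer with the corpus becomes an all-zero row and is
  still scored; only a query shorter than k is refused (flagged
  `unclassifiable`).
* Ambiguous IUPAC letters are kept verbatim inside tokens; they produce
  rare vocabulary entries rather than being masked, which preserves
  determinism and costs only vocabulary width.
* Default k = 7; the CLI exposes k and the sweep command measures the
  accuracy/AUROC surface over k × algorithm. Matrices are CSR integers.

## Tuning loop

Each proposed hyperparameter vector is scored by its mean accuracy over a
stratified, shuffled 5-fold cross-validation with `random_state=2020`
(fixed fold plan, so fold assignment is identical across proposals and
runs). The search space is `max_depth` ∈ [5,10] (integer), `gamma` ∈ [0,1],
`learning_rate` ∈ (0,1] sampled on [1e−3, 1] to avoid the degenerate zero
endpoint, `n_estimators` ∈ [100,400] (integer). Ties are broken by mean
macro AUROC, then by the smaller ensemble.

The optimizer is written in-package: `init_points` uniform draws (default
5) followed by `n_iter` guided proposals (default 25) from a Gaussian
process (Matern ν = 5/2, fixed length scale 0.25 on the unit cube,
normalized outputs) maximizing expected improvement over a seeded
512-candidate set. The fixed length scale is deliberate: with the handful
of observations a realistic budget provides, marginal-likelihood fitting
degenerates toward flat kernels and adds nondeterministic optimizer noise.
A pure random-search strategy is available (`strategy="random"`). A
proposal whose cross-validation fails scores −∞, is logged, and the search
continues. One master seed fixes the proposal stream, the train/test
split, and the engine seed; the CV fold plan is fixed by its own
`random_state`.

During every fit the engine may stop early: 10% of the fitting subset is
split off (stratified) as a validation set and boosting stops after 50
rounds without log-loss improvement (configurable, off when the inner
split is infeasible for the class sizes at hand). This bounds training
cost on easy data without changing the search space.

## Metrics

Per-class metrics use the one-vs-rest reduction: accuracy, sensitivity
(= recall = TPR = TP/(TP+FN)), specificity (TN/(TN+FP)), FPR
(= 1 − specificity), precision (TP/(TP+FP)), F1 (harmonic mean). The
overall multiclass accuracy is always computed on raw labels, never through
OvR. Zero-denominator cases (e.g. a class never predicted) return 0.0 with
a `degenerate` flag and a warning instead of raising, so reports on
imbalanced data always complete.

ROC curves are computed per class over the thresholds induced by the
distinct predicted probabilities (with a sentinel above the maximum) and
integrated trapezoidally; this equals the Mann–Whitney concordance
probability with ties counted ½, which the tests verify against a
brute-force pairwise oracle and against scikit-learn. The macro AUROC is
the unweighted mean over classes present in the truth; absent classes give
NaN and are excluded with a warning. Macro averaging is the default for
precision/recall/F1; support-weighted aggregates are reported alongside
because either convention is common in published tables.

## Synthetic corpus generator

The generator emulates the statistical structure of repository barcode
data: one root sequence (uniform ACGT) per dataset; per species an ancestor
of length L_s ~ Uniform[L_min, L_max] (default 200–2000) taken as a root
prefix with substitutions at the between-species rate d (default 0.05);
per record the ancestor with independent substitutions at the
within-species rate μ (default 0.005) and optional indels (default off —
length variation already comes from ancestor lengths and the feature model
is alignment-free). Substitutions pick uniformly among the three
alternative bases, so every flagged position truly changes; per-record
substitution counts are Binomial(L, μ), which a test checks to within
three standard errors. Class sizes are explicit or drawn log-uniform over
[10, 800] to mimic the long-tailed imbalance of real reference sets; the
bundled `termitomyces_profile()` reproduces the exact class sizes of a
published 17-species corpus (1704 sequences).

A star phylogeny (one ancestor, iid descendants) is the simplest model with
the required within/between divergence contrast. What it does not emulate:
real ITS secondary structure and compositional bias, chimeras, sequencing
error profiles, shared polymorphism between related species, and
phylogenetic correlation among species. Passing the recovery tests
therefore shows the pipeline separates classes whose k-mer profiles differ
at the configured rates — not that any particular accuracy transfers to
real repository data. μ > d is allowed (with a warning): it is a useful
stress regime in which classes overlap heavily and accuracy should and
does degrade.

## Problem sizes used in the checks

The species-recovery study runs at 17 species × 20 sequences, ancestor
lengths 200–800, d = 5%, μ = 0.5% (and a contrast arm at μ = 20%), k = 7,
search budget 5 + 10. These sizes keep a full tuned training run on the
order of a minute or two while leaving the qualitative regime intact:
~16 k-wide vocabularies, strong class structure, and a 20% stratified
holdout of 4 records per class. Unit fixtures are smaller (4–6 species,
k = 4–5) because they exercise contracts, not learning capacity.

## Numerical and degenerate-input choices

* Integer hyperparameters are rounded to the nearest integer inside their
  bounds; proposals live on the unit cube and are mapped affinely.
* `filter_min_count` removing every record, an all-empty token corpus, an
  empty prediction batch, mismatched label vectors, and non-normalized
  probability rows are hard errors naming the offender.
* Stratified splitting refuses singleton classes with a message pointing
  at `min_count` — silently merging or dropping them would corrupt
  evaluation.
* A fold-trained model can miss classes present in the full label map; its
  probability matrix is expanded with zero columns so reports always align
  with the dataset's classes.

## Known limitations

* No reverse-complement handling, no spaced or gapped k-mers, no hashing
  vectorizer: vocabulary width grows toward 4^k and the approach is
  intended for k ≤ ~10.
* The Bayesian optimizer is a maximizer over a 4-dimensional box with a
  fixed-scale GP; it is not a general-purpose tuner (no categorical
  dimensions, no parallel proposals).
* Whether published holdout metrics of comparable pipelines come from the
  20% split or from CV folds is often ambiguous; this package computes and
  labels both (`cv_report.tsv` vs `metrics_holdout.tsv`) rather than
  conflating them.
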