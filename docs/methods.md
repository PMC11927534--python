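# Methods

This note documents the models and procedures implemented in `hdestack`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Candidate scoring and base-learner selection

Candidates are compared on out-of-fold (OOF) predictions from a stratified
K-fold split of the training set (default K = 5), so every score reflects
generalization rather than memorization.

**Pairwise diversity.** For two classifiers x and y, the multiclass
predictions are reduced to a 2×2 correct/incorrect contingency table
(a = both correct, b = only x, c = only y, d = both wrong, n = a+b+c+d):

- disagreement `Dis = (b+c)/n` — larger means more diverse;
- Q-statistic `Qs = (ad−bc)/(ad+bc)`;
- interrater kappa `Ks = (p_o − p_e)/(1 − p_e)` with observed agreement
  `p_o = (a+d)/n` and chance agreement
  `p_e = [(a+b)(a+c) + (c+d)(b+d)]/n²`;
- correlation `Cor = (ad−bc)/√((a+b)(a+c)(c+d)(b+d))`.

Qs, Ks and Cor are association measures: *smaller* values mean more
diversity, and the composite index uses `1 − value` for them so that larger
always means more diverse. A metric whose denominator vanishes for a pair
(e.g. Qs when ad+bc = 0) is excluded for that pair only, with a log entry;
a metric that is degenerate for the whole cohort is skipped with a warning,
and if *every* metric degenerates (all candidates agree everywhere) the
diversity index falls back to uniform shares — the cohort carries no
diversity information.

**Composite indices.** With M candidates and T = 4 diversity metrics,
`d_{x,t}` sums candidate x's (direction-corrected) pairwise values over the
other M−1 candidates, and

    Dci_x = Σ_t  d_{x,t} / Σ_y d_{y,t} .

The per-metric share normalization makes metrics with different scales
commensurable. Two scalings are exposed: `scale="raw"` (the default) keeps
the share sum, so the indices average T/M across candidates and match the
magnitudes conventionally reported for six-candidate cohorts (≈0.48–0.77);
`scale="normalized"` divides by T so the indices sum to one. Ordering is
identical under either scaling, and ordering — not magnitude — is the
contract the tests pin down. The performance composite `Pci_x` applies the
same share construction to accuracy, macro precision, macro recall and F1
(F1 is computed from the macro P and R as `2PR/(P+R)`, the convention used
when a composite table reports a single P and R per model).

**Comprehensive score.** `P_x = r·Dci_x + (1−r)·Pci_x` with r = 0.5 by
default, weighting diversity and performance equally. Ranking is
descending with deterministic tie-breaks: higher Pci first, then model
name. The top-K ranked candidates become the base learners (K = 3 by
default; the ensemble-size sweep utility reproduces the
rise-then-fall behaviour of test performance in K).

## Stacking

Base learners are scikit-learn estimators: logistic regression (LR),
decision tree (DT), RBF-SVM (SVM, no probability calibration — its
meta-features are one-hot predictions), k-NN (KNN), Gaussian process
classifier (GP) and a one-hidden-layer MLP. The GP is wrapped in a
stratified fit-subsample cap (400 rows, fixed RBF kernel, no kernel
optimization) because its cost is cubic in the training size; this is a
cost-control choice and slightly handicaps the GP candidate on large
training sets.

Meta-features are OOF class-probability blocks, one per base learner, so
no row is ever predicted by a model trained on it. The meta-learner is a
multinomial logistic regression — a deliberately simple combiner whose
coefficients yield per-base-learner weights: the mean |coefficient| over
each base's probability block, normalized to sum to one. Bases are
refitted on the full training table for prediction.

## The HDE optimizer

Hyperparameters live in a unit hypercube; `ParamSpace` decodes genomes
(continuous: affine or log-affine map; integer: round after the map;
categorical: floor(g·k), clamped). Defaults for the candidate spaces: LR
C ∈ [1e−3, 1e2] (log); DT max_depth ∈ [2, 20]; SVM C ∈ [1e−2, 1e2] and
gamma ∈ [1e−4, 1e1] (log); KNN k ∈ [1, 30]; GP length-scale ∈ [1e−2, 1e2]
(log); MLP hidden ∈ [8, 256] and alpha ∈ [1e−6, 1e−1] (log).

One generation: compute population diversity D_t (mean pairwise Euclidean
distance) and the convergence indicator c_t, set F and CR, then mutate,
cross over and select each individual. Specifics:

- **c_t** is the relative change of the best fitness over a 5-generation
  window, `|f_best(t) − f_best(t−5)| / max(|f_best(t−5)|, ε)`; the window
  matches the scale of the rule's thresholds (0.05, 0.1). Early
  generations, with no window yet, use c_t = 1 (full exploration).
- **Adaptive F/CR**: three-branch rule on c_t (F = 0.2/0.3/0.5 + 0.5r with
  r ~ U[0,1]; CR = 0.95/0.9/0.7) and/or linear inflation as diversity
  collapses (F ← F_base + ΔF(1 − D_t/D_max), likewise CR). `adapt_mode`
  selects the mechanism; the default `both` draws F and CR from the
  convergence rule and then applies the diversity shift — the two
  mechanisms are presented side by side without a stated composition, and
  additive composition keeps each rule's range intact. F is clamped to
  (0, 1.2], CR to (0, 1]. D_max is fixed at the initial population's mean
  pairwise distance so the shift starts at zero and grows as the
  population contracts.
- **Strategy schedule**: thirds of the run — rand/1 (exploration), then
  current-to-best/1 (balance), then best/1 and best/2 alternating by
  generation parity (exploitation). Donors are clipped to the unit cube;
  the r-indices of each strategy are distinct and exclude the current
  individual.
- **Crossover**: binomial with a forced j_rand coordinate, guaranteeing at
  least one donor component.
- **Selection** is greedy one-to-one and *strict*: the trial replaces the
  parent only when strictly better. On the piecewise-constant (plateau)
  objectives that discrete hyperparameters induce, accepting equal-fitness
  trials lets the population drift together and kills exploration.
- **Diversity restoration**: if D_t falls below 0.25·D_max, the worst
  quarter of the population is re-seeded uniformly (and evaluated) before
  the generation proceeds. Diversity monitoring exists precisely to
  prevent premature convergence; re-seeding is the action taken at full
  collapse, where inflating F can no longer help because the difference
  vectors themselves have collapsed. Set `diversity_floor=0` to disable.
- A genome whose objective raises is scored −∞ and logged; the trace of
  best-ever fitness is monotone by construction.

The stacking objective is the mean stratified-CV accuracy of the stack
under the decoded hyperparameters, with all fold seeds fixed so the
objective is deterministic for a given genome. Reference configuration:
population 20, 50 generations.

## Shapley explanations

Each base learner is explained separately on its class-probability output
with interventional Shapley values: the value of a coalition S is the mean
model output with features in S taken from the sample and the rest from a
background dataset (a k-means summary of the training data, 50 centers by
default). Two engines:

- **exact** — full coalition enumeration (2^p model calls), used up to
  p = 16 features; exact Shapley values.
- **sampling** — marginal contributions along random feature orderings,
  drawn as antithetic pairs (each ordering followed by its reverse) to
  reduce variance. Any single ordering's contributions telescope to
  f(x) − E[f(background)], so the local-accuracy identity
  Σ_j φ_j + base = f(x) holds to machine precision for *any* number of
  orderings; more orderings improve the per-feature attributions.

The stack's explanation is the weighted sum of the per-base tensors and
base values, using the meta-learner-derived base weights. This explains a
weight-mixture surrogate of the stack (the weighted sum of base-learner
probabilities), not the exact meta-learner composition — the standard
procedure for attributing ensemble decisions to input features, and an
approximation documented as such. Exports: a feature ranking by mean |φ|
(per predicted class, per fixed class, or averaged over classes) with
per-point (φ, feature value) scatter data, and per-sample force
breakdowns (signed contributions sorted by |φ|, base value, f(x)).

Tolerances asserted by the tests: local-accuracy residual ≤ 1e−6 for the
exact engine and ≤ 1e−2 for sampling (both are observed at ~1e−16 because
of the telescoping construction); aggregation is exactly linear in each
base tensor.

## Spectral preprocessing and band selection

Savitzky–Golay smoothing uses window 11 and polynomial order 2 by default
— standard near-infrared practice that preserves the peak/valley
morphology at 1 nm sampling; the window must be odd, larger than the
order and no larger than the band count. Min–max ranges are learned on
training rows only (no leakage); held-out values may leave [0, 1] and are
logged, constant features map to 0. Fusion concatenates the morphological
block first, preserving modality tags. Splits are stratified.

The band selectors share an inner cross-validated regression on one-hot
class indicators (5-fold): PLS with up to 10 components for CARS and BOSS
(whose rankings come from |PLS coefficients|), ridge-stabilized MLR for
SPA's chain scoring (the classical choice; SPA's chains are already
nearly orthogonal). SPA grows a projection chain from each candidate
starting band via incremental Gram–Schmidt — selected columns are
linearly independent by construction — and returns the (start, prefix)
with minimal RMSECV; for large grids a seeded random subset of 30 starts
is used. CARS keeps `r_i = a·e^(−k·i)` of the bands per Monte-Carlo run
(two-constant schedule fixed by its endpoints: 100% at the first run, 2
bands at the last) and resamples among them with probability proportional
to |coefficient|; retained counts are non-increasing by construction, and
the subset with minimal RMSECV wins. BOSS accumulates normalized
|coefficients| from bootstrap band sub-models into soft weights
(non-negative, summing to one), samples shrinking candidate sets by
weighted random sampling (shrink factor 0.8), and stops when RMSECV stops
improving (patience 5); the bands of the minimal-RMSECV sub-model are
returned. Morphological selection wraps scikit-learn's
`mutual_info_classif`, `RFE` (logistic estimator on standardized columns,
step 0.2) and tree-importance top-k (`SFM` spirit, top-k rather than a
fixed threshold so the selected count is exact); default k = 15.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a multimodal seed study:
smooth reflectance curves (Gaussian bumps of ~40 nm width at the named
peak/valley positions on a linear baseline) shared across classes, with
class effects entering both as per-peak amplitude rescalings and small
additive offsets — giving band selectors localized signal — plus i.i.d.
Gaussian band noise. The morphological block mixes 15 class-informative
columns (named after the field's descriptors: E, r, hist0, contrast,
g_dev, a_dev, h_mean, …; the remainder m16…m51) with pure-noise columns,
all on deliberately heterogeneous scales (four decades). One global seed
drives everything; each modality derives its RNG by a fixed offset so
changing one modality's parameters never perturbs the other's draw.

Default effect sizes (class_shift_sd = 0.004, noise_sd = 0.012
reflectance units, morph_effect_size = 0.5 standardized units) are set so
the six candidates' CV accuracies span roughly 40–80% on the default
11-class design — a regime where ensembling is neither trivial nor
hopeless, mirroring the difficulty spread reported for comparable
real-data cohorts. The generator does not model instrument physics
(scatter, baseline drift, band-wise correlated noise), between-kernel
morphological correlations, or class-conditional covariance structure;
passing tests therefore demonstrate correctness and the method's internal
contracts, not field performance on real spectra.

## Problem sizes used in the test suite

The suite exercises the full 11-class × 150-per-class design with a 10 nm
wavelength grid (216 bands) for the stacking-improvement checks, 25 nm
grids for pipeline smoke tests, and 150 × 200 matrices with three
injected informative bands for selector-recovery checks; the optimizer's
reliability is measured on an exhaustively enumerable 24-assignment space
(two categorical parameters, 4 × 6, so every assignment occupies equal
genome volume). These sizes keep the whole suite to a few minutes while
preserving each contract being tested.

## Known limitations

- Dci/Pci magnitudes depend on the chosen scale convention; only orderings
  are comparable across studies.
- The weighted-Shapley aggregate explains the probability-mixture
  surrogate, not the exact stacked decision function.
- The GP candidate's fit-subsample cap biases its candidate scores
  downward on training sets larger than the cap.
- CARS/BOSS are stochastic; their selected sets vary across seeds, and
  only behavioural properties (recovery, monotone retention, RMSECV
  contracts) are guaranteed.
- The CLI persists fitted stacks with pickle; artifacts are only loadable
  with compatible library versions.
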