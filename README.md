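# hdestack

Diversity-aware stacking ensembles with adaptive differential-evolution
hyperparameter tuning and weighted Shapley explanations, built for
multimodal crop-phenotyping classification — the motivating task is seed
variety identification from fused morphological (geometric / texture /
color) and near-infrared hyperspectral (350–2500 nm reflectance) feature
tables.

## What it does

Distinguishing visually similar seed varieties is a many-class, small-sample
problem where no single classifier dominates. `hdestack` builds a stacking
ensemble whose base learners are chosen to be *good but different*:

1. **Preprocessing** — Savitzky–Golay smoothing of reflectance curves,
   min–max normalization of heterogeneous morphological scales, stratified
   train/test splitting, and feature-level fusion (concatenation) of the
   two modality blocks.
2. **Feature selection** — chemometric wavelength selectors implemented in
   full (SPA successive projections, CARS competitive adaptive reweighted
   sampling, BOSS bootstrap soft shrinkage, all scored by the RMSECV of an
   inner PLS regression on one-hot class indicators), plus thin wrappers
   for morphological selection (mutual information, RFE, tree-importance).
3. **Base-learner selection** — every candidate (LR, DT, SVM, KNN, GP, MLP)
   is scored on out-of-fold predictions with four pairwise diversity
   measures derived from the 2×2 correct/incorrect contingency table
   (disagreement Dis, Q-statistic Qs, interrater kappa Ks, correlation
   Cor) and four performance measures (accuracy, macro precision/recall,
   F1). Share-normalized sums give a diversity composite index Dci_x and a
   performance composite index Pci_x; candidates are ranked by the
   comprehensive score

       P_x = r · Dci_x + (1 − r) · Pci_x,   r = 0.5,

   and the top-K become the base learners.
4. **HDE optimization** — an improved differential evolution tunes the
   stack's hyperparameters: F and CR adapt to a convergence indicator c_t
   (F = 0.2/0.3/0.5 + 0.5r by branch; CR = 0.95/0.9/0.7) and inflate as
   population diversity collapses (F ← F_base + ΔF·(1 − D/D_max)); mutation
   strategies are stage-scheduled (rand/1 → current-to-best/1 → best/1 and
   best/2); selection is greedy one-to-one. The objective is the stack's
   mean stratified-CV accuracy.
5. **Explanation** — each base learner gets an interventional Shapley
   attribution of its class-probability output (exact coalition enumeration
   for small feature counts, antithetic permutation sampling otherwise);
   the per-base attributions are combined as a weighted sum using base
   weights read off the multinomial logistic meta-learner's coefficients,
   and exported as summary rankings and per-sample force breakdowns.

The reference dataset of the motivating study is not public, so the package
ships a first-class synthetic generator that reproduces its structure:
11 classes × 150 reflectance curves on a 1 nm grid with peaks near
863/1105/1295/1680/2015 nm and valleys near 980/1175/1450/1780/1915 nm,
class-dependent peak amplitudes and offsets, plus a 52-column morphological
block with class-dependent means and deliberately heterogeneous scales.

## Worked example

```python
import hdestack as h

cfg = h.SynthConfig(n_classes=5, n_per_class=40, wavelength_step=25, seed=0,
                    class_shift_sd=0.006, noise_sd=0.01, morph_effect_size=0.6)
morph, spectra, labels = h.make_dataset(cfg)
spec = h.sg_smooth(spectra, window=11, polyorder=2).to_feature_table(labels)
fused = h.fuse(morph, spec)
train, test = h.split(fused, 0.7, seed=0)
train, ranges = h.minmax_normalize(train)
test, _ = h.minmax_normalize(test, ranges=ranges)

model = h.HDEStackingModel(train, k_base=3, n_folds=5, seed=0)
results = model.fit()          # fit(optimize_hyperparams=True) adds HDE tuning
print(results.summary())
print(results.evaluate(test))
```

prints

```
HDE-Stacking results
============================================================
Candidate ranking (comprehensive score):
       Dci    Pci    P_x  rank
LR  0.5652 0.7243 0.6448     3
DT  1.0337 0.5557 0.7947     1
SVM 0.4986 0.7245 0.6115     6
KNN 0.7482 0.6355 0.6918     2
GP  0.5470 0.6977 0.6223     5
MLP 0.6074 0.6623 0.6348     4

Selected base learners (top 3): DT, KNN, LR
Meta-learner base weights:
  DT: 0.2158
  KNN: 0.3369
  LR: 0.4473

{'accuracy': 95.0, 'precision': 95.48, 'recall': 95.0, 'f1': 95.24}
```

Reading the ranking: the decision tree is individually the weakest candidate
(lowest Pci) but disagrees most with everyone else (highest Dci), so the
comprehensive score still ranks it first — exactly the "good but different"
trade the method is designed to make. The final metrics are percentages on
the held-out test split; the base weights are the meta-learner-derived
mixture used later for weighted Shapley explanation
(`results.explain(test.values[:10])`).

The same workflow is scriptable:

```bash
hdestack run --preset paper --seed 0 --out runs/demo   # full pipeline
hdestack report runs/demo                              # collate report.md
```

plus stage-wise subcommands (`simulate`, `preprocess`, `select`, `fuse`,
`rank`, `optimize`, `fit`, `evaluate`, `sweep-k`, `explain`).

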