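# Methods

## The problem

Peak-picking software exports one feature list per LC-MS sample: a table
of detected features, each with a mass-to-charge ratio (m/z), retention
time, peak height and peak area. Because acquisition time differs
between samples, these lists have *different lengths* and occupy the
m/z axis sparsely — they cannot feed a supervised classifier directly,
and naive per-row alignment is meaningless. `mzwin` turns such ragged
collections into a fixed-width feature matrix, selects a minimal
discriminative set of m/z windows, classifies, and maps the selected
windows back to mass intervals that nominate candidate biomarkers.

## Sliding-window feature construction

The cohort is scanned for its global m/z range `[start, stop]`. A grid
of `n = floor((stop − start)/step)` contiguous windows of width `step`
(Da) is laid over the range; window `i` covers
`[start + i·step, start + (i+1)·step)` and the final window is closed on
the right at `stop`, so every in-range peak belongs to exactly one
window (`i = min(floor((mz − start)/step), n − 1)`). Each sample is then
represented by the per-window **arithmetic mean** of its peak heights
(or, separately, peak areas). Windows in which a sample detected no
peak are recorded in a missing mask and filled with 0 — the natural
mass-spectrometric reading of "no signal detected"; no other imputation
or normalization is applied.

The floor convention is the one under which the range 54–1223 Da yields
1169, 779 and 584 windows at steps 1.0, 1.5 and 2.0 respectively.
Degenerate inputs are defined rather than rejected: a range narrower
than one step yields a single window covering the whole range.

`step` is the method's key tunable. Too narrow and the matrix stays
sparse, noisy and high-dimensional; too wide and distinct species are
averaged together. The pipeline treats a list of steps as a first-class
sweep and reports, per step, how few windows suffice for the best
classifier.

## Chi-square window scoring

Two scoring forms rank windows by association with the binary class
label (positive = disease):

* **frequency** (default): per class, observed `O` = sum of the
  feature's values in that class, expected `E` = class sample-proportion
  × total sum; the score is `Σ (O−E)²/E` over the two classes. This is
  the intensity-weighted chi-square that scikit-learn's feature
  selection computes on non-negative data (the implementation here is
  independent; the library is used only as a cross-check in the tests).
* **contingency**: the 2×2 presence/absence table (A, B, C, D) of
  "window non-missing" against class, scored as
  `(AD − CB)²/((A+C)(B+D)(A+B)(C+D))`. This form deliberately omits the
  sample-size factor N of the classical Pearson statistic; `× N`
  recovers Pearson exactly (a tested identity), and since N is constant
  across windows the ranking is unchanged. A `classical` flag applies
  the factor for interoperability. Zero marginals (constant feature,
  absent class) score 0 and are flagged degenerate.

Ranking is deterministic: descending score, ties broken by ascending
window index.

## Minimal subset search

For `k = 1…k_max` (default 20) and each model of the zoo, the model is
fit on the training rows restricted to the top-`k` ranked windows and
scored on a validation partition. The result is the smallest `k` —
ties resolved to the earliest model in the fixed zoo order — attaining
the maximum validation accuracy; that one choice is then evaluated a
single time on the test partition. The validation partition is carved
(stratified, seeded, default 25 %) from the training side of the split,
so subset and model selection never touch the test set.

## Model zoo

Ten classifiers run with fixed, untuned hyperparameters: random forest
(10 trees), decision tree, RBF-kernel SVM (cache 200 MB), 5-nearest
neighbours, L2 logistic regression, LightGBM (100 estimators), Gaussian
naive Bayes, bagging (100 estimators), AdaBoost (50 estimators) and a
one-hidden-layer MLP of width 32. Models exposing probabilities score
the positive class by `predict_proba`; the SVM uses its decision
function — the rank-based AUC needs only an ordering.

Two parameter choices deserve a note. A "penalty" setting is sometimes
quoted for decision trees, which have no such parameter; library
defaults are used there. Likewise a smoothing `alpha` exists only for
the count/binary naive-Bayes variants, while the constructed features
are continuous mean intensities — Gaussian NB is the appropriate
variant and has no alpha. No model scales its input except the MLP,
whose spec standardizes features before fitting: a gradient-trained
network simply diverges on raw intensity scales (≈10²–10⁴ counts), and
pipelining a standardizer with a neural network is universal practice;
tree, neighbour and margin models see the raw values the windowing
produced. LightGBM's `min_child_samples` is lowered to 5 so the
boosting can split on cohorts of tens rather than thousands of samples.

## Split protocols

Three strategies, all deterministic given a seed: a stratified
train:test **ratio** split (e.g. 2:1 or 7:3); **fixed per-class counts**
on the training side (e.g. 29+29 train vs 14+30 test); and **batch
holdout**, where one acquisition batch forms the entire test set —
the hardest protocol, since batch effects then separate training and
test distributions.

## Evaluation metrics

Precision, specificity, sensitivity, accuracy, F1 and the Matthews
correlation coefficient are computed from the confusion counts with
positive = disease. Any 0/0 cell is reported as 0 with a degenerate
flag rather than raising, keeping sweep loops alive on tiny validation
folds. AUC uses the rank formula
`(Σ ranks of positives − M(M+1)/2)/(M·N)` with ascending mid-ranks for
ties, which makes it exactly the Mann–Whitney U estimator; the tests
verify the identity against exhaustive concordant-pair counting and
against scipy/scikit-learn.

## Back-mapping and marker nomination

A selected window index recovers its mass interval as
`low = index·step + start`, `high = low + step`. Within an interval,
candidate marker masses are nominated by traversing the masses common
across samples: peak m/z values are rounded to `decimals` places
(default 3 — substances whose masses agree at that precision are
treated as one species), groups reaching a `min_support` fraction of
samples are kept, and candidates are ranked by the absolute difference
in per-class support, falling back to the standardized mean-intensity
difference on ties. `min_support` defaults to 1.0 ("common to all
samples") but is exposed because a disease-specific marker is, by
construction, absent from one class.

## Synthetic cohorts

The generator emulates exactly the data structure the method exists to
handle, with defaults frozen to a two-batch serum study: 59 disease and
43 healthy samples (batch 1: 21 P / 20 N, unshifted; batch 2: 38 P /
23 N, +0.02 Da m/z shift, ×1.3 intensity), m/z range 54–1223 Da,
Poisson(500) background peaks per sample at uniform m/z, log-normal
peak heights (location 5.0, scale 0.5 in log space; area = height × a
uniform RT-width factor), retention times uniform on 0–30 min. One
disease-specific marker is planted at m/z 113.02: present in every
disease sample, absent in health, elevated 6 log-SD (≈20-fold) over
background — the strongly separable regime in which one or two windows
suffice for near-perfect classification, matching the intended use
case of the pipeline. Planted masses carry sub-rounding-precision
jitter (±4·10⁻⁴ Da) so they aggregate to one rounded mass.

Two structural extras support harder scenarios: `joint_pairs` plants a
pair of masses carried *both* by every disease sample but *exactly one*
(at random) by each healthy sample, with a shared intensity elevation —
neither mass separates the classes alone, only the pair does, which
exercises the subset search beyond k = 1; `anchor_range` places one
baseline peak at each end of the configured range so the realized
global scan equals the configured range.

What the generator does **not** model: raw spectra or chromatographic
peak shape, isotope envelopes, adducts, retention-time drift,
correlated (non-uniform) background chemistry, or heavy-tailed
contaminant species. Passing tests therefore demonstrate that the
pipeline recovers planted signal under realistic sparsity, length
variation and batch structure — not that it would rank biologically
confounded markers correctly in real serum data.

## Numerical choices and edge cases

* Window assignment clamps to the last window, so a peak exactly at the
  grid stop is never orphaned.
* Non-numeric, non-finite or negative rows in feature-list CSVs are
  dropped with a logged count, not fatal; a file with zero valid rows
  is an error. CSV floats are read with round-trip precision so writing
  and re-reading a peak list is exact.
* Chi-square of a constant-zero column and AUC of a single-class vector
  are degenerate: the former scores 0, the latter raises (the caller
  has no meaningful ranking question).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` and scikit-learn `random_state`; identical
  config + seed reproduces cohorts, splits and fits bit-for-bit on the
  same platform.
* Test problem sizes are deliberately modest (cohorts of tens of
  samples, grids of a few hundred to ~1200 windows) — large enough to
  exhibit sparsity and batch structure, small enough that the whole
  suite, including a 100-replicate recovery study, runs in minutes.

## Known limitations

* The frequency chi-square compares raw intensity sums, so without
  normalization a strong batch intensity factor inflates scores of
  densely occupied windows; batch-holdout evaluation reveals the cost.
* Mean aggregation dilutes a marker's signal when background peaks
  co-occupy its window; at very fine steps sparsity dominates instead.
  The step sweep exists precisely because neither extreme wins.
* The minimal-subset criterion is validation accuracy on a single
  stratified fold; with small validation sets the chosen k is noisy
  around its expectation (no cross-validation, by design fidelity to
  the original protocol).
* Presence/absence scoring ("contingency") ignores intensity entirely;
  it is the faithful-to-formula alternative, not the default.
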