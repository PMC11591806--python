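# Methods

This note documents the models and procedures implemented in `bcdpipe`,
the parameters that matter, the numerical choices, and what the synthetic
experiments do and do not show.

## Problem setting

The pipeline targets two-class diagnosis from small numeric tables: one
row per case, a handful of bounded ordinal features (the motivating data
are fine-needle-aspirate cytology scores on a 1–10 integer scale), and a
benign/malignant label. Two data problems dominate at this scale:
uninformative features, and *outliers* — training cases whose feature
vector is inconsistent with their label (measurement error, transcription
error, mislabeling). Both inflate the variance of nearest-neighbour and
margin-based classifiers, so the pipeline filters both before training.

## Pipeline

Per cross-validation fold: fit min–max normalization on the training
fold; rank features by information gain on the (normalized) training
fold and keep a subset; reject outlying training instances with CORT;
train the ensemble on what remains; evaluate on the untouched test fold.
No statistic is ever fit on test data.

### Min–max normalization

Each feature is mapped to (x − min)/(max − min) with the extremes taken
from the training fold only. Constant features map to 0 (division
guard); out-of-range test values are clipped to [0, 1]. Fitting on the
training fold only is a deliberate fold-hygiene choice: normalizing the
pooled data before splitting would leak test-fold extremes into training.

### Information-gain feature selection

IG(f) = H(y) − Σ_v (n_v/n) H(y | f = v), in bits, computed on discrete
feature values. Integer-valued features on at most `bins` distinct values
are used as-is (the natural treatment for 1–10 cytology scores);
continuous features are discretized into `bins` equal-width bins over the
observed training range (default `bins = 10`). The default selection
policy keeps features with gain strictly above the mean gain, falling
back to all features when gains are uniform, so the selection is never
empty; a `top_k` policy is available. The cutoff is a design choice — an
above-mean filter adapts to however many features happen to be
informative without a tuned k.

## CORT: combined outlier rejection

### Quick rejection phase (QRP)

Per class *cl*, compute the feature-wise mean μ_cl and sample SD σ_cl
(d − 1 denominator; the SD is floored at `sd_epsilon`, default 1e−8, to
guard constant features; singleton classes get the floor everywhere).
Each instance is scored against *its own class*:

    score(I, cl) = mean_j |I(f_j) − μ_cl(f_j)| / σ_cl(f_j)

The per-feature deviations are aggregated by their mean so scores are
comparable across dimensionalities. The rejection threshold is

    trd = Σ_cl trd_cl,   trd_cl = mean over class-cl instances of score(I, cl)

and an instance is rejected iff score > trd (strict, so ties survive).
Two modes exist: `standardized` (default) measures both the scores and
the threshold in SD units, which makes the filter invariant to
per-feature rescaling; `literal` uses raw mean absolute deviations on
both sides instead. Summing contributions over classes means trd grows
with the number of classes; for the two-class problems targeted here the
effect is simply a more permissive threshold than either class alone
would set. If every member of a class lands above trd, the class's
lowest-scoring instance is retained (with a logged warning) so
downstream stages always see all classes.

A worked 1-D example, single class {0, 0.1, −0.1, 5}: μ = 1.25, sample
SD = 2.5013, standardized scores {0.4997, 0.4598, 0.5397, 1.4992},
trd = 0.7496 — exactly the extreme value 5 is rejected.

### Binary Harris hawk optimization (BHHO)

The accurate phase needs a combinatorial optimizer over instance
subsets. BHHO is a swarm method: a population of "hawks" stalks the
"prey" — the elitist incumbent, i.e. the best solution evaluated so far.
Per hawk and iteration, the prey's escape energy

    G = 2 G0 (1 − J/it_max),  G0 ~ U(−1, 1)

dispatches the move: |G| ≥ 1 explores (a jump referenced to a random
hawk, or to prey minus population mean); otherwise one of four sieges
runs, selected by |G| ≷ 0.5 and a fresh escape draw e ~ U(0, 1). The two
dive sieges (e < 0.5) are greedy — a candidate Y (and on failure a
Lévy-flight perturbation Z = Y + Q ∘ Lévy, Mantegna construction with
exponent β = 1.5 and the conventional 0.01 prefactor) replaces the hawk
only when its fitness improves; the other moves are accepted
unconditionally. The hard-siege dive references the population mean
rather than the hawk itself.

Binarization: each continuous update vector is clipped to [lb, ub]
(default ∓4), mapped coordinate-wise through the sigmoid transfer
S(x) = 1/(1 + e^(−x)), and sampled into bits (bit = 1 iff a uniform draw
falls below S(x)). **The sampled bits are stored as the hawk's new
position.** Keeping positions binary — rather than carrying the
continuous vector forward — holds update magnitudes near the sigmoid's
steep region, so sampling stays stochastic and diverse throughout the
run; with continuous positions the coordinates saturate at the bounds
(bit probabilities 0.018/0.982) and the search effectively freezes. The
difference is measurable: on random fitness tables of dimension ≤ 10
(population 10, 200 iterations) the binary-position variant matches
exhaustive search in ≈97% of seeded runs versus ≈82% for the
continuous-position variant. The bounds lb/ub still shape the continuous
intermediate (and the mean-referenced exploration term).

All randomness flows from one seeded generator: identical seed, config
and fitness give a bit-identical result. The trace of incumbent fitness
is non-increasing by construction (elitism).

### The accurate rejection phase (ARP) objective

The QRP survivors (the |N| candidates) are encoded as a bit vector,
1 = keep. The fitness to minimize is

    fitness(R) = α · γ(R) + δ · (|N| − |R|)/|N|,  α = 0.99, δ = 1 − α

γ(R) is the error of a k-nearest-neighbour evaluator (k = 5, Euclidean
distance on the current feature set) *built from the selected instances
R and assessed over all candidates*: every candidate, selected or not,
is classified by its k nearest selected instances, itself excluded.
Masks with |R| < k + 1 or missing a class are invalid (+inf). The
all-ones mask is injected into the initial population, so by elitism the
result is never worse, under this objective, than keeping every QRP
survivor.

Two design points deserve emphasis, because the obvious alternatives
fail measurably:

* **γ is assessed over all candidates, not only over R.** A
  leave-one-out error computed on R alone lets the optimizer delete its
  own mistakes: any small internally-consistent subset (|R| ≈ k + 1 per
  class) reaches γ = 0, and the search collapses the training set to a
  handful of prototypes (measured clean-instance retention 7–40% on the
  synthetic recovery experiment). Assessing all candidates means a
  rejected instance still has to be explicable by the instances that
  remain.
* **The parsimony term counts rejections, not selections.** This phase
  is an instance *rejector*: the natural transplant of the
  wrapper-selection parsimony ("fewest selected features") is "fewest
  rejected instances" — prefer the edit that perturbs the training set
  least at equal error. Penalizing the *kept* fraction instead actively
  rewards discarding data and produces the same prototype collapse.

**Known limitation — boundary carving.** With the conventional 99:1
weighting, removing one residual nearest-neighbour error pays for up to
α/δ ≈ 100 rejections. On overlapping classes the optimum therefore
smooths the class boundary aggressively: clusters of clean
boundary-region instances whose removal fixes a neighbour's vote are
worth rejecting. On the synthetic recovery conditions (n = 120, b = 5,
5% mean-shift outliers, class separation 4 within-class SDs) the final
kept set excludes 100% of planted outliers but retains only ≈72–81% of
clean instances depending on seeds, and a stronger optimizer retains
*less*, because deeper carving genuinely lowers this objective. Raising
δ would protect retention but the 99:1 ratio is the conventional
operating point for this fitness family and is kept. Users who want
pure outlier removal with guaranteed retention should rely on the QRP
alone or raise δ in the configuration.

## Ensemble classification and evaluation

Three base classifiers are trained on the cleaned table: Gaussian naive
Bayes, KNN (k = 5, Euclidean) and an SVM (RBF kernel, C = 1) —
hyperparameters deliberately left at field-standard defaults and echoed
in every report. Prediction is by majority vote; with three voters over
two classes no tie is possible (a configurable tie order covers
hypothetical even ensembles). Metrics use malignant as the positive
class: precision TP/(TP+FP), recall TP/(TP+FN), accuracy
(TP+TN)/total, error = 1 − accuracy, F1 = 2PR/(P+R). Zero-denominator
cells are defined as 0 with a logged warning. Percentages are
*truncated* (never rounded) to three decimals, matching the reporting
convention of the comparison tables this package reproduces (e.g.
precision 98.4% and recall 98% give F1 = 98.199%). Cross-validation is
stratified (default 5 folds, shuffled by the run seed); plain unshuffled
partitions would risk degenerate folds on imbalanced data.

## Synthetic data generator

`generate(SyntheticSpec)` draws two isotropic Gaussian classes on a
bounded range, clips to the range, and plants a known fraction of
outliers; the planting mask is returned so recovery is measurable.
Defaults: 60 instances per class, 5 features, value range (1, 10),
within-class SD 1, class-mean separation 4 (Euclidean) — an overlap
level giving a few percent nearest-neighbour error, comparable to the
difficulty of the cytology data the pipeline targets. Outlier modes:
`label_flip` (label inverted), `mean_shift` (every feature displaced by
max(2.5, 4/√b)·SD with random sign, guaranteeing ≥ 4 SD Euclidean
displacement even after clipping), `uniform_noise` (features redrawn
uniformly). One RNG stream per call, derived from the spec seed.

What the generator does *not* model: feature correlations, ordinal
discreteness (unless `integer_values` is set), class imbalance, and
structured missingness of real cytology data. Passing the synthetic
recovery tests shows the pipeline removes gross planted anomalies and
preserves reproducibility; it does not certify performance on real
clinical data.

## Numerical choices and degenerate inputs

* SD floor `sd_epsilon = 1e−8` (post-normalization scale) for constant
  features and singleton classes.
* QRP rejection is strict (score > trd): tied instances survive.
* Whole-class rejection guard: the class's lowest scorer is retained.
* Evaluator ties (even k) fall back to the single nearest neighbour.
* Rows with missing values are dropped at load, never imputed, with
  logged counts; the WBCD dialect's `?` marker and 2/4 class codes are
  handled natively.
* Invalid optimizer masks signal through +inf fitness rather than
  exceptions, keeping the search total.
* Problem sizes in the test suite and the acceptance script (40
  optimizer seeds at dim ≤ 10, 20 recovery seeds at n = 120, CV at
  n = 200) are chosen so the full suite completes in well under a minute
  while keeping the Monte-Carlo bounds meaningful.
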