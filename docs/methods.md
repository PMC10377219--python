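# Methods

This note documents the models, the numerical choices and the design
decisions behind `stresslstm`, and states plainly what the synthetic
data can and cannot show.

## 1. The classifier

### Sequence construction

Each subject is a fixed-length sequence of T standardized scalars, one
per screened feature, in the canonical schema order (gender, age,
height, weight, sleep duration, pulse rate, SBP, DBP, BMI, drinking,
smoking — restricted to the selected subset, so T = 9 under the default
screening outcome).  This is a deliberate reading of "feature
attention": with one feature per time step the attention distribution
is a distribution over *features*, and the attention layer has
something to do.  The alternative — a single step carrying a 9-wide
input — would make the bidirectional encoder and the attention softmax
vacuous (softmax over one position is identically 1).  Per-step input
width m is kept general in the code but is 1 everywhere in practice.

Continuous features are z-scored with mean/SD estimated on the training
split only; binary features are mapped to {0, 1} and z-scored the same
way.  The fitted scaler is stored in the checkpoint sidecar, so a saved
model reproduces its forward behaviour bitwise.

### Peephole cell

The peephole variant lets the input and forget gates see the previous
memory cell and the output gate see the *current* memory cell (the
standard peephole output-gate convention).  With the peephole flag off
the memory-cell columns of the gate matrices disappear and the cell is
the plain LSTM; a structural test verifies that zeroing those columns
reproduces the plain cell step-for-step to 1e-12.  In the plain-LSTM
reading we take the cell update c_t = f_t⊙c_{t−1} + i_t⊙c̄_t (the
obvious recurrence; a variant with x_{t−1} in place of c_{t−1} appears
in some writeups and is dimensionally inconsistent for m ≠ n).

### Encoder, attention, decoder

* Both directional cells start from zero states; the per-position
  combined state is h_k = tanh(V [h→_k; h←_k] + k).  The combiner
  nonlinearity is tanh, consistent with every other candidate
  nonlinearity in the architecture.  Attention consumes these
  *combined* states, not the raw directional ones.
* Attention scores are plain dot products e_k = cᵀh_k of the decoder
  memory against each combined state; the softmax subtracts the maximum
  score before exponentiating, so scores of magnitude 1e3 (and far
  beyond) produce finite, exactly normalized weights.  The softmax
  index runs over the T encoder positions.
* The decoder runs a single step by default: from a zero state the
  first attention pass is uniform (c = 0 gives equal scores), the
  context is the mean encoder state, and one peephole step plus the
  dense head and sigmoid produce the class probability.  The number of
  steps is exposed (`decoder_steps`), attention being recomputed from
  the current memory vector at every step; the gradient check covers
  the multi-step path too.

### Initialization

Glorot-style uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases,
forget bias 1.  The forget-bias offset is standard practice to keep
memory flowing early in training and is stated here because it is part
of the reproducibility contract, all of which hangs on a single integer
seed.

### Parameter counting

`count_parameters` reports the exact number of trainable scalars from
the shape rules (for n = m = 1, T = 9: 50 = two encoder cells of 15, a
combiner of 3, a decoder cell of 15 and a 2-parameter head).  It also
reports the conventional nominal figure 7·(n² + nm + n) quoted for this
architecture family; that formula does not follow from any shape
arithmetic consistent with the equations above, and it is surfaced for
reference only, never used in computation.

## 2. Training

Binary cross-entropy with probabilities clipped to [1e−7, 1−1e−7] for
numerical safety, plus an L2 penalty λ_r·Σw² over weight matrices only
(biases, the combiner offset k and the head bias are excluded).
Defaults follow the published configuration 1: learning rate 5e−4,
batch 768, dropout 0.2, 150 epochs, λ_r = 1e−5; configuration 2
(3e−4 / 1024 / 0.3 / 100) is available as a preset.  Three choices the
published settings leave ambiguous:

* **Adam vs momentum.**  The optimizer is Adam with β₁ = 0.9 (the
  "decay factor"), β₂ = 0.999, ε = 1e−8, bias-corrected moments.  The
  configuration records a `momentum` field because the published table
  lists one, but it is inert under Adam; plain SGD is available behind
  `optimizer="sgd"` for anyone who reads "stochastic gradient descent"
  literally.
* **Dropout placement.**  "For the LSTM layer" is read as the encoder's
  combined per-step states h_k, with inverted scaling, training only.
* **Split protocol.**  A seeded stratified 80/20 train/validation split;
  the fraction is configurable.

Backpropagation is hand-written through the entire graph: head →
decoder cell(s) → attention (both into the encoder states and into the
scoring memory vector) → dropout → combiner → both directional cell
chains.  The single most important test of the package compares every
analytic gradient against central differences (step 1e−6) at relative
1e−5 on an (n=3, T=4, batch 5) model.  Components whose magnitude is
below ~1e−4 are compared with an absolute tolerance of 1e−9 instead:
central differences in float64 carry rounding noise of order
eps·|J|/step ≈ 1e−10, so demanding relative 1e−5 of a 1e−8 gradient
would test the oracle's arithmetic, not the backpropagation.

The hidden width n is not part of the published settings; the package
default is 16 (64 felt oversized for T ≤ 11 scalar steps; accuracy on
synthetic cohorts is insensitive between 8 and 32).

## 3. Screening

Welch's unequal-variance t-test is used for the continuous variables.
Whether the original analysis used Student's pooled or Welch's test is
not determinable from the published table (no SDs are printed); Welch
is the safer default and the two agree closely at these group sizes.
The chi-square test is Pearson's without Yates continuity correction:
on the published drinking table the corrected test gives p ≈ 0.005
while the uncorrected one gives the printed 0.004 (and 0.001 for
gender, <0.0005 for smoking), so the uncorrected test is demonstrably
the one that reproduces the published values.  All tests are two-sided;
no multiple-testing correction is applied (none was in the source
analysis).  Degenerate inputs (constant samples, zero table margins)
raise a named error rather than returning NaN.

Formatted summary output prints p-values in fixed-point with three
decimals (so 6.6e−6 prints as 0.000); full precision is retained in
the report objects.

## 4. The synthetic cohort generator

The generator emulates a two-group case/control cohort whose group
means, category proportions and sizes match the reference summary
table: 640 low- and 633 high-stress subjects (the sums of the
published gender counts; the table's stated total of 1280 is
inconsistent with its own counts and the generator simply takes
n_low/n_high as inputs).  A companion helper reproduces the full
population imbalance (2529 / 651, total 3180).

* **Distributions.**  Continuous variables are truncated normals within
  physiologic bounds (age [18, 75] years, sleep [1, 14] h, SBP
  [70, 230] mmHg, ...).  Truncation would bias the mean (for age by
  about −3.5 years, since the 75-year bound sits ~1.1 SD above the
  target), so the location parameter is solved with a root finder so
  the *post-truncation* mean equals the target.  Binary variables are
  Bernoulli draws of the second category.  Labels are group membership
  at sampling time (a two-component mixture): all class signal lives in
  the between-group shifts, which matches the case/control framing.
* **Standard deviations** are not published and are generator
  calibration constants: age 15, height 6, weight 4, sleep 1.2, pulse
  8, SBP 14, DBP 20 (kg, cm, h, bpm, mmHg respectively; all
  configurable).  They were chosen — once, from the power arithmetic,
  not from test outcomes — so that at n = 640/633 the seven shifted
  continuous variables have two-sample power ≥ 0.98 while DBP (shift
  1.07 mmHg) rejects rarely, reproducing the reference significance
  pattern in expectation.  Two of them (weight, DBP) are deliberately
  not population-realistic: a weight SD of ~11 kg would leave the
  0.95 kg group shift undetectable at this n (expected |z| ≈ 1.5), and
  a DBP SD of ~10 mmHg would make the planted null reject half the
  time (expected |z| ≈ 1.9).  The generator calibrates signal-to-noise
  ratios, not marginal realism.
* **BMI** is never sampled; it is recomputed as weight/(height/100)²
  after sampling so the derived-variable identity holds exactly.  Its
  printed group means (24.08 / 24.16) are *unreachable* under that
  identity from the printed height/weight means — independent sampling
  gives ≈24.8 per group, and even a maximal height–weight correlation
  cannot close the gap, so the printed triple is internally
  inconsistent under any distribution.  What the generator preserves is
  what matters for screening: a tiny between-group BMI delta
  (≈0.06 kg/m²), so BMI behaves as the second planted null.  The
  large-sample calibration test therefore covers the ten sampled
  quantities' means/proportions (within 4 standard errors at n = 10⁴
  per group) and checks BMI through the identity and the delta.
* **Exact-recovery rate.**  Across seeded replicates at n = 640/633,
  screening selects *exactly* the nine reference variables in roughly
  55–70% of cohorts.  That rate has a structural ceiling: the gender
  and drinking proportions are pinned to the published counts, whose
  effect sizes at this n give chi-square power ≈ 0.91 and ≈ 0.82, so
  even with perfect continuous separation and perfect nulls the
  per-replicate probability cannot exceed ≈ 0.7.  Observed failures are
  almost always a DBP or BMI false rejection or a drinking/gender miss,
  which is exactly the behaviour a borderline-powered analysis would
  show on resampled data.

**What passing tests do and do not show.**  The generator produces
independent, truncated-normal features with the right group moments; it
does not model survey weights, sampling strata, feature correlations
(beyond the height/weight→BMI identity), measurement error, or the
four-level stress questionnaire the binary label collapses.  Tests
passing on these cohorts demonstrate that the pipeline's statistics and
optimization are correct and that the model can extract linear
mean-shift signal; they say nothing about accuracy on real survey data,
where the published headline percentages additionally depend on
unstated splits and stochastic training, and are not reproducible from
the published information (the published confusion counts themselves
imply accuracy 83.9% and precision 92.4% for the proposed model,
inconsistent with the headline 75.54% / 74.26%; the package computes
metrics from the counts and leaves the inconsistency visible).

## 5. Evaluation

The positive class is high stress.  `classify` maps probability ≥
threshold to "high" (ties to the positive class, documented).  Metrics
with zero denominators are reported as `None` with a warning, never
coerced to 0 — a classifier that never predicts the positive class has
*undefined* precision, and silently scoring it 0 corrupts comparisons.
The six published confusion rows ship as a small CSV fixture; tests
verify the four formula identities on each row and cross-check against
scikit-learn on random label/prediction streams.

## 6. Reproducibility and problem sizes

Every stochastic stage (simulation, splitting, initialization,
shuffling, dropout) draws from substreams derived from one integer
seed, so pipelines, fits and the acceptance script are bit-for-bit
repeatable.  The shipped verification runs use intentionally small
problem sizes — gradient checks at n=3/T=4, learnability at 400
records/8 hidden units/60 epochs, screening recovery over 20 cohorts of
1273 — chosen as the smallest sizes at which each property is
informative; all scale up linearly in the obvious parameters.

## 7. Known limitations

* Single-threaded numpy; no GPU path.  Fine for survey-scale tables,
  not for large sequence corpora.
* Fixed-length sequences only; the text/sentence framing of the
  attention mechanism is deliberately mapped onto tabular features.
* Binary labels only; the four-level stress item is out of scope.
* No class re-weighting despite the 2529/651 population imbalance
  (the source analysis used none); recall on the minority class
  suffers accordingly on imbalanced cohorts.
* The nominal 7·(n²+nm+n) complexity figure is reported but cannot be
  reconciled with the actual shapes; trust `count_parameters(...).exact`.
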