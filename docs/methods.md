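# Methods

## Model

`spo2cast` forecasts a patient-stay's SpO2 one step ahead from its own
recent history, at two horizons: 5 minutes (native monitoring frequency)
and 30 minutes (the 5-minute series downsampled by 6). Saturation is
modeled in the transformed space

    p = 1 − exp((SpO2 − 100)/10),

which maps [0, 100]% monotonically (decreasing) onto [0, 1 − e^−10] and
stretches the clinically dense region near 100%. All training targets,
losses, waveform errors (MSE, Pearson r) and the decision threshold live
in p space; predictions are inverse-transformed with
SpO2 = 100 + 10·ln(1 − p) for display. The hypoxemia threshold is
SpO2 < 92%, i.e. p > 1 − e^−0.8; the full-precision constant is used
internally and 0.55067 is its 5-decimal display form. The boundary case
of exactly 92% is non-hypoxemic (strict inequality); an inclusive
variant is available via `classify_hypoxemia(..., inclusive=True)`.

The forecaster is a recurrent network over the lag window (default 2
prior values, configurable 1–5): a batch-normalization layer on the
scalar input feature, then either a shallow stack of 2 LSTM layers
(default widths 256 and 16) or a deep stack of 5 layers (default taper
256/128/64/32/16 — the deep widths are a package choice, ending at the
shallow stack's 16), dropout 0.1 after every LSTM layer, and a 1-unit
linear output. Training minimizes MSE with Adam (default learning rate
0.001, batch size 256) for 100 epochs; each epoch holds out a random 10%
validation split, and the weights from the epoch with the lowest
validation loss are restored at the end. Hyperparameters are selected by
3-fold cross-validation over {shallow, deep} × {0.001, 0.01, 0.1},
minimizing mean held-out MSE; a candidate whose training diverges scores
as infinitely bad rather than aborting the search.

Prediction is teacher-forced: every input row uses *observed* prior
values, never the model's own previous prediction, so the forecast of an
N-point series has N − lags values aligned to indices lags..N−1.
Predictions are clipped into [0, 1) so they are always
inverse-transformable.

### Why a hand-rolled network

No deep-learning framework is assumed at run time. The LSTM stack,
batch norm, dropout and Adam are implemented in numpy (`spo2cast._nn`)
with exact backpropagation through time (sequences are only lags long),
following Keras conventions: gate order i/f/g/o, unit forget-gate bias,
Glorot-uniform kernels, orthogonal recurrent kernels, BN eps 1e−3 /
momentum 0.99, Adam eps 1e−7. The analytic gradients are verified
against central finite differences in the test suite (relative error
< 1e−3 at eps = 1e−6, dominated by finite-difference truncation).
Single-threaded numpy makes training bit-reproducible for a fixed seed.

### Validation-split reading

"A random validation set at each epoch" is read literally: the split is
re-drawn every epoch from a seeded generator. This makes the best-epoch
criterion noisy (each epoch's validation loss is measured on a different
sample), so `resplit_validation=False` offers a fixed seeded split as a
practical alternative. The default follows the literal protocol.

### Cross-validation folds

Folds are drawn over pooled rows by default, matching training on the
concatenated cohort vector. Because lag windows never cross stay
boundaries but rows of one stay can land in different folds, a
`stay_level=True` option (GroupKFold on stay identity) is provided to
rule out within-stay leakage.

## Preprocessing conventions

- **Pipeline order is fixed**: regularize → transform → smooth →
  (downsample) → supervise. Smoothing always happens at 5-minute
  resolution; the 30-minute series keeps indices 0, 6, 12, ….
- **Regularization** anchors the grid at the first observation's
  timestamp and forward-fills; a leading all-missing stretch is
  backfilled with the first available value, so the output never has
  missing values. Irregular data are regularized before smoothing (the
  filter assumes a uniform grid).
- **Warm-up rule** read literally: the first window−1 (=4) points pass
  through unsmoothed; an expanding-window head is available behind
  `expanding_head=True`.
- **Exclusions** apply to the regularized 5-minute grid: entirely blank
  stays ("blank") and stays under 61 points, i.e. 5 hours inclusive of
  endpoints ("too_short").
- **Ground-truth labels** for evaluation are computed from the smoothed,
  transformed series — the model's own target space — so that label and
  forecast are thresholded identically. Raw-space labeling can be done
  by thresholding before preprocessing if a sensitivity analysis needs
  it.

## Evaluation

Per stay: confusion counts of thresholded forecast vs thresholded truth,
accuracy, sensitivity, specificity, PPV, plus waveform MSE and Pearson r
in p space. Undefined-value semantics are explicit: sensitivity is
undefined (None) iff the stay has no true events, specificity iff it has
no true non-events, PPV iff no positive predictions, and Pearson r iff
either series is constant. Undefined values are excluded from
distribution summaries, which report the excluded count alongside mean,
median, quartiles (numpy linear-interpolation convention), Tukey
1.5·IQR fences, whisker data values and outliers.

Pooled results sum the per-stay counts — provably identical to flattening
all label streams and counting once — and report FPR = FP/(FP+TN),
FNR = FN/(FN+TP) and pooled sensitivity/specificity/PPV/accuracy.

Two cohort-level statistics mirror the standard analysis: Welch's
unequal-variance t-test comparing mean true-event counts between stays
with sensitivity < 0.5 and ≥ 0.5 (restricted to stays where sensitivity
is defined; "not computable" is reported when a subgroup has fewer than
2 stays), and a Pearson chi-squared test of independence (df = 1, no
continuity correction) between cohort label and pooled
hypoxemic/non-hypoxemic timepoint counts. Both delegate to scipy.

## Synthetic cohort generator

The simulator produces the *structure* of ICU oximetry records, not
physiology: per stay, a baseline drawn from N(97, 1)% clipped to ≤100,
desaturation events arriving as a Poisson process (default 0.5/h) whose
dips are piecewise-exponential (descent and recovery limbs with time
constant duration/4; a linear triangle is available), depth uniform on
(5, 25)%, duration uniform on (15, 60) min; additive Gaussian sensor
noise (sd 0.6%); independent Bernoulli missingness (5%); stay lengths
triangular on (330, 720, 1440) min. Irregular (ward-like) sampling thins
the dense 5-minute grid with a keep probability chosen so the median
inter-observation gap matches `median_gap_minutes` (default 25).
Baseline + events + noise are computed first, then clipped to [0, 100].
Subpopulations (e.g. a ventilated-like group with a higher event rate)
are declared as label/size/override tuples. Each stay's random stream is
seeded by (cohort seed, global stay index), so cohorts are
byte-identical across runs and machines.

Defaults were chosen once as a realistic test world: with them,
hypoxemic timepoints are roughly 5–20% of a stay, between the ventilated
and non-ventilated prevalences typical of critical-care cohorts. The
generator does **not** emulate circadian structure, autocorrelated
sensor artifacts, block missingness (optional block dropout is not
implemented), care-event-driven interventions, or any dependence of
sampling on patient state. A green end-to-end test therefore establishes
that the pipeline's machinery is correct and that the learned model
outperforms persistence on plausibly structured data — not that any
particular clinical performance level would be attained on real
cohorts.

## Numerical choices

- Transform domain errors (SpO2 outside [0,100], p outside [0,1)) raise
  rather than clip; the forecaster's own outputs are clipped into [0, 1)
  before inverse transformation.
- Cohort CSVs are written with 17 significant digits and read with
  pandas' round-trip float parser, so write→read is bit-exact.
- Model archives are .npz files with a JSON header carrying a format
  tag (`spo2cast-lstm/1`), estimator parameters, history and best epoch;
  a tag mismatch raises instead of silently misreading.
- Pipeline randomness flows from one root seed split into per-stage
  seeds (simulate/split/forecaster/cv) via `numpy.random.SeedSequence`;
  the manifest records all of them.
- Tests train reduced-width networks (e.g. 16/8 units, ≤80 epochs) so
  the suite runs in well under a minute on one CPU; the package defaults
  remain the full 256/16, 100-epoch configuration.

## Known limitations

- Teacher forcing only: no recursive multi-step rollout, by design.
- Single-feature input (prior SpO2 only); no vitals, demographics or
  ventilator settings.
- Batch-norm inference uses running statistics accumulated during
  training (standard inference behavior); statistics are not re-frozen
  per test stay.
- The undefined-metric conventions mean cohort summaries are computed on
  the defined subset; both the summary and the excluded count are
  reported so either reading can be reconstructed.
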