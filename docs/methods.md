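# Methods

## Problem and approach

`neurocast` implements a two-step, predict-then-diagnose procedure for
anticipating whether an individual will remain cognitively normal (CN) over
the next 2–4 years using only five inexpensive neuropsychological tests:
MMSE, ADAS Q4, ADAS Cog-11, ADAS Cog-13 and FAQ.

1. **Predict.** For each test separately, a univariate sequence-to-one
   recurrent network forecasts the next visit's score from the preceding
   visits. Four networks per test are trained, one per target position
   5–8 of the visit grid (months 36, 48, 60, 72). Applied recursively —
   each prediction is appended to the input window for the next model —
   they extend a subject's four observed values (months 0, 6, 12, 24) out
   to month 48 or 72 without ever reading an actual value past month 24.
2. **Diagnose.** A per-horizon perceptron maps the five predicted scores
   at the horizon to a CN / non-CN (MCI or AD pooled) call.

The chained construction is the essential design constraint: the month-48
and month-72 diagnoses are functions of months 0–24 only, which is what
makes the output a genuine 2–4-year forecast rather than a cross-sectional
classification.

## Visit grid and curation rules

Visits lie on the fixed grid {0, 6, 12, 24, 36, 48, 60, 72} months; the
admissible sequence lengths 4, 6, 8 end at months 24, 48, 72. Visits are
treated as equally spaced integer steps: the cohorts this emulates have no
time irregularities, so calendar gaps carry no extra information.

Retention filters per (subject, test, length): at most two missing scores,
a present final score, and — where a label is consumed — a present
final-visit diagnosis. Missing entries are imputed with the arithmetic
mean of the observed entries of that sequence; the same rule fills one or
two gaps and preserves the sequence mean exactly. Scores are normalised
to [0, 1] by dividing by the test maximum (MMSE/30, ADAS Q4/10,
ADAS Cog-11/70, ADAS Cog-13/85, FAQ/30).

Forecast rows are shuffled by seed and split 80/20 (floor on the training
count). Diagnosis training sets are class-balanced: floor(0.8 × minority)
rows from the minority class plus an equal-size seeded sample of the
majority class, everything else becoming validation. The diagnosis-set
filters are applied jointly over all five tests — a subject failing the
sequence filters for any single test is dropped.

In the combined chain the months-0–24 prefix is imputed **from the
prefix's own observed values only**. Using the full 8-visit mean would
leak post-month-24 information into the forecast; the sentinel-corruption
test (`test_no_leakage_from_post_month24_values`) pins this down.

## Network architectures and training

No deep-learning framework is assumed: `neurocast.nn` is a small float64
numpy kit (dense layer, LSTM layer with manual backpropagation through
time, Adam, MSE loss) implementing exactly the two architectures used.
Analytic gradients are verified against central finite differences in the
test suite.

**Forecaster** — two stacked LSTM layers (default 32 and 16 units) and a
dense scalar head; rectified-linear activations throughout, including the
LSTM candidate/cell activations (conventional sigmoid gates). The dense
head's bias starts at 0.5 so the relu output unit begins live in the
middle of the normalised range; predictions are clipped to [0, 1] because
scores are bounded. Loss is MSE with Adam (default learning rate 2e-3,
batch 16, 200 epochs). `n_restarts` independent initialisations (default
5) are trained and the candidate with the lowest validation MSE is kept,
ties resolved by restart order; "best model" is read as lowest validation
MSE, the only monotone accuracy notion available for a regression without
a threshold. No early stopping; per-epoch loss histories are retained so
divergence is auditable.

**Diagnoser** — a perceptron with four hidden relu layers and a scalar
sigmoid output, trained with MSE loss (kept for architectural fidelity
even though cross-entropy is the convention for classification). Default
hidden widths (32, 16, 8, 4) for the month-24/48 models and (24, 12, 8, 4)
for month 72 — small capacity matched to the few hundred training rows
these cohorts yield. The decision threshold is 0.5 with ties assigned to
non-CN; with balanced training a symmetric threshold is the natural
choice. The month-24 model is trained and reported but plays no role in
the chain.

Every source of randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical configs reproduce identical
tables, splits, weights and metrics bit for bit.

## Synthetic cohort generator

Real cohorts of this kind are access-restricted, so the generator is a
first-class module with known ground truth. Each subject draws one of
three latent classes (defaults 50 % / 25 % / 25 %):

* `stable_cn` — baseline severity s0 ~ U(0.02, 0.15), no drift;
* `converter` — s0 ~ U(0.12, 0.28) (a mild prodromal deficit, as observed
  in subjects who later convert), drift switching on at month 24;
* `decliner` — s0 ~ U(0.28, 0.50), drift from baseline.

Severity evolves linearly; each test score is an affine map of severity
into its raw range (MMSE falls, ADAS/FAQ rise), plus a class- and
test-specific raw-unit trend, plus Gaussian noise with a shared per-visit
component (loading 0.6) that induces cross-test correlation. Scores are
rounded to integers and clipped to their ranges. Default progressor
drifts — MMSE −1.2, ADAS Q4 +0.6, ADAS Cog-11 +2.5, ADAS Cog-13 +3.0,
FAQ +2.0 points/year — sit in the clinically reported range for MCI-to-AD
progression (MMSE typically loses 1–3 points/year); noise SDs (0.5–1.8
raw points) are modest so trajectories remain slow and trend-dominated.
The diagnosis at each visit is a deterministic function of severity
(CN < 0.25, AD > 0.60, MCI between), so label recovery is well-defined.
Missing scores and diagnoses are injected completely at random (default
5 % each) — the mean-imputation rule assumes nothing stronger.

What the generator does **not** emulate: informative dropout, practice
effects, floor/ceiling measurement artefacts, covariate (age/education)
effects, biomarkers, and reversion (misdiagnosis) noise in the labels.
Passing tests therefore demonstrate that the pipeline recovers structure
of this trend-plus-noise form, not performance on any real cohort.

## Evaluation conventions

Predictions on a held-out test cohort — subjects never used in any
training or validation split, with complete length-8 data for all five
tests — are tabulated against the reference diagnosis at exactly the
horizon month (no carry-forward). Category accuracy divides agreements by
the subjects in that predicted category whose reference is present;
overall accuracy pools agreements over all subjects with a reference.
These denominators are forced by the published count tables this
convention reproduces (33/39 = 84.62 %, 15/19 = 78.9 %, 48/58 = 82.76 %).
Percentages are displayed with half-up rounding at two decimals; exact
values are kept internally.

Descriptive statistics mirror the figure-level summaries: cutoff splits
(boundary scores count as normal, since cutoffs are stated as ≥/≤),
same-side-of-cutoff agreement between actual and predicted scores,
boxplot-style group ranges (linear-interpolation quartiles), and Student-t
mean confidence bands (appropriate at n ≈ 50–120 validation sizes; bands
from different validation sets are never bridged).

## Problem sizes

The shipped experiment (`ExperimentConfig`) simulates 600 subjects,
reserves up to 66 fully observed subjects as the held-out test cohort
(mirroring the scale of the original 66-subject test set), and trains the
20 forecasters with 120 epochs × 2 restarts and the 3 diagnosers with 150
epochs — sizes chosen so a complete run finishes in a few minutes on one
CPU while leaving the recovery margins wide. The acceptance-style checks
use 500 noiseless linear-trend sequences for forecaster recovery and a
600-row wide-margin separable set for diagnoser recovery.

## Known limitations

* The latent model is linear in severity; no plateau or accelerating
  decline, so long-horizon extrapolation is easier than in real cohorts.
* Labels are noise-free functions of severity; real clinical adjudication
  disagrees with itself at a non-trivial rate, which would cap attainable
  accuracy.
* The diagnoser is trained on actual scores but applied to predicted
  scores; any systematic forecaster bias shifts its operating point. This
  mirrors the original construction and is retained deliberately.
* Univariate forecasters ignore cross-test information at prediction
  time; only the diagnoser fuses the five tests.
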