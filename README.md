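# neurocast

Predict-then-diagnose modelling of cognitive decline from longitudinal
neuropsychological test scores.

Alzheimer's disease progresses slowly, and inexpensive paper-and-pencil
tests — MMSE, ADAS Q4, ADAS Cog-11, ADAS Cog-13 and FAQ — track that
progression well enough to be useful screening markers. `neurocast`
implements a two-step neural procedure for deciding, from four observed
visits (months 0, 6, 12, 24), whether a subject is likely to remain
cognitively normal (CN) two to four years later:

1. **Forecast.** Per test, two-layer LSTM sequence-to-one regressors
   predict the normalised score at the next visit. Applied recursively
   (each prediction feeds the next model), they extend the four observed
   values x₀…x₂₄ to x₃₆ᵖʳᵉᵈ, x₄₈ᵖʳᵉᵈ and on to x₇₂ᵖʳᵉᵈ — using no actual
   data past month 24.
2. **Diagnose.** A per-horizon multi-layer perceptron (four hidden relu
   layers, sigmoid output) maps the five predicted scores at month 48 or
   72 to a CN / non-CN call (MCI and AD pooled), thresholded at 0.5.

Scores are normalised by their test maximum; sequences with more than two
missing values or a missing final value are dropped, the rest mean-imputed;
diagnosis training sets are class-balanced. Predictions on a held-out
cohort are scored against the reference diagnosis with missing-aware
contingency accuracies: per predicted category,
`accuracy = agreements / (subjects − missing references)`, and overall,
`accuracy = total agreements / subjects with a reference`.

Because the longitudinal clinical data this method targets are
access-restricted, the package ships a first-class synthetic cohort
generator (latent linear severity, per-test affine maps, correlated noise,
MCAR missingness) so the whole pipeline is trainable and testable from
scratch. The neural layers themselves are a small, fully deterministic
numpy implementation (`neurocast.nn`) with gradient checks in the test
suite — no deep-learning framework required.

Intended users: researchers in biostatistics / epidemiological modelling
who want a reproducible, inspectable reference implementation of recursive
multi-step score forecasting plus downstream classification, with known
ground truth to probe it on.

## Worked example

```python
from neurocast import (
    ExperimentConfig, GeneratorConfig, run_experiment,
)

report = run_experiment(ExperimentConfig(
    generator=GeneratorConfig(n_subjects=200, seed=3),
    forecaster_epochs=40, forecaster_restarts=1, diagnoser_epochs=80,
    seed=3,
))
for horizon in (48, 72):
    rows = report["combined"][horizon]["rows"]
    for row in rows:
        print(horizon, row["predicted"], row["n_subjects"], row["accuracy_pct"])
    print(horizon, "overall", report["combined"][horizon]["overall_accuracy_pct"])
```

prints

```
48 CN 13 84.62
48 non-CN 15 100.0
48 overall 92.86
72 CN 9 100.0
72 non-CN 19 89.47
72 overall 92.86
```

i.e. on a 200-subject simulated cohort, 13 held-out subjects were
predicted to stay CN at month 48 (84.62 % agreed with the reference
diagnosis), 15 were predicted non-CN (100 % agreed), for 92.86 % overall
agreement; the month-72 chain reads analogously. The same `run` is
available from the shell:

```bash
neurocast simulate --n-subjects 600 --seed 0 --out cohort.csv
neurocast run --n-subjects 600 --seed 0 --out report.json
```

Lower-level building blocks (`extract_sequences`, `impute_sequence`,
`build_forecast_dataset`, `train_forecaster_restarts`, `chain_forecast`,
`train_diagnoser`, `score_against_reference`, ...) are all public; see
`docs/methods.md` for the model, its assumptions and the design choices.

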