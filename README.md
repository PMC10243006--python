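# survcloak

Privacy-enhancing survival curves for federated analysis.

A Kaplan–Meier survival curve is disclosive: every step marks the time at
which a group of subjects had an event, and when that group has size one an
adversary who holds a previously released curve can attribute a new drop to
a specific individual (the *release-and-join* attack). `survcloak`
implements the server-side defence used in federated biomedical platforms:
each site releases only a *privacy-enhanced* curve — the product-limit
estimate passed through LOESS smoothing with an automatically selected
span, with censoring markers suppressed and minimum-count disclosure guards
enforced — and provides the evaluation harness to measure how much the
defence actually degrades the attack.

## What is inside

- **Kaplan–Meier estimation** (`KaplanMeierEstimator`, `fit_km`): the
  product-limit estimate Ŝ(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) over the distinct
  observed times, with step-function evaluation and plotting vertices.
- **LOESS smoothing with AICc span selection** (`LoessSmoother`,
  `select_span`): local linear/quadratic fits with tricube weights; the
  span minimises the corrected AIC for nonparametric smoothers,
  AICc = log(σ̂²) + 1 + 2(ν+1)/(n−ν−2), where ν is the trace of the hat
  matrix and σ̂² = RSS/n.
- **Anonymisation alternatives** (`ProbabilisticAnonymizer`,
  `DeterministicAnonymizer`): seeded percentage-of-value noise with a
  monotonicity repair, and k-nearest-neighbour centroid replacement.
- **Pipeline and federation** (`privacy_enhanced_curve`,
  `federated_curves`, `disclosure_guard`, `render_curve`): guard →
  estimate → anonymise → clip → suppress censor marks, applied
  independently per site.
- **Privacy evaluation** (`loo_attack_experiment`, `leave_one_out_delta`,
  `step_identifiability`, `ablation_study`): singleton-step
  identifiability, leave-one-out curve deltas with inflection
  localisation, and subsample-and-remove-one ablation studies.
- **Synthetic data** (`generate`, `veteran_like_fixture`): right-censored
  Weibull/exponential cohorts with independent censoring, including a
  137-subject cohort shaped like the classic veteran lung-cancer data.

The estimators follow scikit-learn conventions (`fit`, `predict`/
`transform`, `get_params`, trailing-underscore fitted attributes) and
compose with sklearn tooling; module-level functions are thin wrappers.

## Worked example

```python
import numpy as np
from survcloak import (veteran_like_fixture, fit_km, privacy_enhanced_curve,
                       step_identifiability, loo_attack_experiment)

cohort = veteran_like_fixture(seed=1)          # 137 subjects, ~7-9% censored
raw = fit_km(cohort)
print(len(raw), step_identifiability(raw).size)
# 137 125        -> 125 of 137 observed times are singleton-event steps,
#                   each attributable to one subject on the raw curve

release = privacy_enhanced_curve(cohort, "loess")
print(release.method, round(release.params["span"], 3), len(release))
# loess 0.08 138 -> the AICc-selected span on the 138-point grid
#                   (137 distinct times plus the (0,1) anchor)

attack = loo_attack_experiment(n_replicates=100, seed=1)
print(attack["raw_success_rate"], attack["smoothed_success_rate"])
# 1.0 0.23       -> the raw release pins the joiner's event time in 100/100
#                   replicates; on the smoothed release the nearest detected
#                   inflection lands within 2 time units only 23/100 times
```

A command-line interface mirrors the library:

```sh
survcloak simulate --n 137 --seed 1 --output cohort.csv
survcloak curve --input cohort.csv --method loess --output curve.json --plot curve.svg
survcloak federate --sites siteA.csv --sites siteB.csv --outdir out/
survcloak eval loo --input cohort.csv --index 12 --report loo.json
```

Exit codes: 0 success, 2 validation error, 3 disclosure-control refusal.

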