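# mooddyn

Temporal-weighting models of momentary mood in probabilistic reward tasks.

When people report their momentary mood during a gambling task, they
integrate over the history of their experiences — but with what temporal
weighting?  The standard *recency* account holds that the latest reward
prediction errors (RPEs) dominate; the competing *primacy* account holds
that early events cast the longest shadow, because expectations are built
from the running history of outcomes and every later expectation re-uses
the early ones.  `mooddyn` implements both accounts (and the variants
between them) as one parametric family, together with everything needed to
compare them end to end on synthetic or locally supplied behavioral data:

- **Model family** — mood at trial t is a baseline plus discounted,
  coefficient-weighted sums of per-trial regressors,
  `M_t = m0 + Σ_v β_v Σ_{j≤t} γ^{t−j} X_v(j)`, where the streams are the
  certain amount C, an expectation term E, and the RPE R = A − E.  The
  recency model sets E to the current gamble's mean; the primacy model
  sets E to the average of all previous outcomes.  Theoretical
  event-influence curves are computed by finite differences.
- **Task simulators** — the three reward environments of the underlying
  experimental design: random RPEs (±2.5), structured blocks (+5 / −5 / +5
  with 30% incongruent trials of magnitude 1.5), and a closed-loop
  structured-adaptive task whose RPEs are set in real time by a
  proportional–integral controller steering mood toward per-block targets.
- **Synthetic participants** — choice policies plus model-driven noisy
  mood raters, so fitting and comparison are testable against known ground
  truth.
- **Group-regularized fitting** — joint maximum-fit estimation across
  subjects with variance penalties on the discount parameter and the
  coefficients (λ_ξ = 10, λ_β = 100 by default), softplus-constrained
  β ≥ 0, L-BFGS with analytic gradients, and multi-start over the
  discount-factor basins.
- **Model comparison** — training error and streaming one-step-ahead
  prediction (refit on ratings 1..k−1, predict rating k), compared across
  subjects with one-sided Wilcoxon signed-rank tests (exact tie-aware null
  at small n), plus model recovery, leave-out validation, and a
  β_E-vs-β_R coefficient contrast.

## Worked example

Simulate ten synthetic participants on the structured task from the
primacy model and fit both principal models
(`examples/simulate_and_fit.py`):

```
simulated 10 sessions of 81 trials / 34 ratings
 primacy: median training MSE 0.00233 (objective 0.7223, converged=True)
 recency: median training MSE 0.00246 (objective 0.8422, converged=True)

beta_E - beta_R across subjects: mean -0.0024, t = -0.50, p = 0.632
```

The generating (primacy) model attains the lower training error and the
lower joint objective; the contrast line asks whether mood tracks
accumulated expectations (β_E) more strongly than surprises (β_R) — at
this small simulated cohort the difference is not significant.  The
training MSE is on the squared unit-mood scale, so ~0.002 means typical
rating errors of about 0.05.

The other scripts in `examples/` each demonstrate one capability —
influence curves, the streaming comparison, the closed-loop adaptive task,
model recovery, and session file I/O — and print a short reading of their
output.  A thin command-line surface (`mooddyn simulate-cohort`,
`fit`, `stream-eval`, `compare`, `recover`, `report`) wraps the same
functions for shell pipelines.

Real behavioral data are supported through `mooddyn.osf_adapter`, which
maps a locally downloaded trial-wise table into sessions via an editable
column-mapping file (`mooddyn.write_mapping_template`); nothing is ever
downloaded by the package.

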