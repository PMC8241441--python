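"""Streaming model comparison: predict each mood rating from its past.

For every rating index k >= 4 the candidate model is refit on ratings
1..k-1 and used to predict rating k; per-subject mean squared errors over
rating indices >= 11 are compared across models with a one-sided Wilcoxon
signed-rank test.  This prospective criterion penalizes overfitting in a
way the training error cannot.
"""

import numpy as np

from mooddyn import (
    FitConfig,
    PRIMACY,
    RECENCY,
    PopulationSpec,
    compare_models,
    simulate_cohort,
    streaming_prediction,
)

pop = PopulationSpec(n_subjects=12, generating_model=PRIMACY)
sessions, _ = simulate_cohort(pop, "structured", seed=3)

cfg = FitConfig(restarts=2)
results = {}
for spec in (PRIMACY, RECENCY):
    res = streaming_prediction(sessions, spec, cfg)
    results[spec.name] = res
    print(
        f"{spec.name:>8}: median streaming MSE {np.median(res.mse):.5f}, "
        f"IQR {np.subtract(*np.percentile(res.mse, [75, 25])):.5f}"
    )

cmp = compare_models(
    results["primacy"].mse, results["recency"].mse, "primacy", "recency"
)
print(
    f"\nprimacy vs recency: z = {cmp.z:.3f}, one-sided p = {cmp.p_value:.4f}"
    f" -> winner: {cmp.winner}"
)
print(
    "Reading: positive z favors the primacy model, which generated these\n"
    "data. At this demo-sized cohort the direction is usually right but\n"
    "may miss significance; the test suite's recovery assessment uses\n"
    "n = 40 per cohort, where both directions separate clearly."
)
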