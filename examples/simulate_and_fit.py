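"""Simulate a small synthetic cohort and fit both principal mood models.

Ten synthetic participants play the structured task (three 27-trial blocks
of +5 / -5 / +5 reward prediction errors); their sparse mood ratings are
generated by the primacy model with known parameters plus rating noise.
Both models are then fit jointly with the group-regularized objective and
compared on training error, and the fitted primacy coefficients are
contrasted (expectation vs RPE sensitivity).
"""

import numpy as np

from mooddyn import (
    FitConfig,
    PRIMACY,
    RECENCY,
    PopulationSpec,
    coefficient_contrast,
    fit_group,
    simulate_cohort,
    training_error,
)

pop = PopulationSpec(n_subjects=10, generating_model=PRIMACY)
sessions, truth = simulate_cohort(pop, "structured", seed=7)
print(f"simulated {len(sessions)} sessions of "
      f"{sessions[0].n_trials} trials / {sessions[0].n_ratings} ratings")

cfg = FitConfig(restarts=3)
for spec in (PRIMACY, RECENCY):
    fit = fit_group(sessions, spec, cfg)
    mse = training_error(fit)
    print(
        f"{spec.name:>8}: median training MSE {np.median(mse):.5f} "
        f"(objective {fit.objective:.4f}, converged={fit.converged})"
    )

fit_primacy = fit_group(sessions, PRIMACY, cfg)
contrast = coefficient_contrast(fit_primacy)
print(
    f"\nbeta_E - beta_R across subjects: mean {contrast.mean_difference:+.4f},"
    f" t = {contrast.t:.2f}, p = {contrast.p_value:.3f}"
)
print(
    "Reading: the generating (primacy) model attains the lower training\n"
    "error; the contrast asks whether mood tracks accumulated expectations\n"
    "more strongly than surprises."
)
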