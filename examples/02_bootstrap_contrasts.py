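"""Bootstrap confidence intervals and tests for group differences.

Amplitude and acrophase are nonlinear in the regression coefficients,
so their uncertainty comes from a parametric bootstrap: simulate from
the fitted mixed model, refit, recompute the marginal means, repeat.
The contrast table reports the pairwise group differences with
percentile CIs, sign-count p-values and significance stars.
"""

from cosinormixed import (
    ModelSpec, bootstrap_cosinor, contrasts_with_ci, fit, means_with_ci,
    parse_emm_formula, simulate_dataset,
)
from cosinormixed.validation import reference_two_group_design

design = reference_two_group_design(n_subjects=60, obs_per_subject=8, seed=7)
dataset, truth = simulate_dataset(design)
result = fit(dataset, ModelSpec(factors=["grp"]))

boot = bootstrap_cosinor(result, parse_emm_formula("~grp"), n_sim=200, seed=1)
print(f"bootstrap: {boot.n_success}/{boot.n_requested} replicates succeeded\n")

print("group-level estimates with 95% percentile CIs:")
cols = ["grp", "mesor", "mesor_lower", "mesor_upper",
        "amplitude", "amplitude_lower", "amplitude_upper", "peak_time"]
print(means_with_ci(boot)[cols].round(3), "\n")

print("pairwise contrasts (a - b):")
report = contrasts_with_ci(boot)
print(report[["contrast", "parameter", "estimate", "lower", "upper",
              "p_value", "stars"]].round(4))
print("\nThe generating difference was 4 ms in amplitude and -0.5 rad in"
      " acrophase; 'acrophase_hours' restates the phase difference as a"
      " peak-time shift in hours.")
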