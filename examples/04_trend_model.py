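"""Fit the three-level adherence-trend model to a simulated cohort.

Simulates a reduced trial (20 clinics x 12 adolescents x 6 months) at the
published coefficients, fits the months-in-participants-in-clinics
logistic model, and prints the recovered fixed effects, variance
components, population-averaged monthly adherence and month contrasts.
"""

from adheremon import (
    SimConfig,
    fit_three_level_logit,
    margins_table,
    simulate_cohort,
    time_contrasts,
)

cfg = SimConfig(n_clinics=20, participants_per_clinic=12, months=6, seed=17)
truth = simulate_cohort(cfg)
obs = truth.monthly.merge(truth.roster[["participant_id", "clinic_id", "arm"]],
                          on="participant_id")
obs["good"] = (obs["category"] == "good").astype(int)

fit = fit_three_level_logit(obs)
print(f"n = {fit.n_obs} participant-months, converged = {fit.converged}")
print(f"intercept {fit.params['const']:.3f} (true {cfg.beta0}), "
      f"clinic variance {fit.sigma2_clinic:.3f} (true {cfg.sigma2_clinic}), "
      f"participant variance {fit.sigma2_participant:.2f} "
      f"(true {cfg.sigma2_participant})")

print("\npopulation-averaged P(good adherence), control arm:")
margins = margins_table(fit)
for _, row in margins[margins["arm"] == "control"].iterrows():
    print(f"  month {int(row['month_index'])}: {row['predicted_probability']:.3f} "
          f"({row['ci_low']:.3f}-{row['ci_high']:.3f})")

contrasts, inter = time_contrasts(fit)
print("\nlog-odds change vs month 1:")
print(contrasts.round(3).to_string(index=False))
print(f"\njoint month x arm interaction: chi2({inter.df}) = {inter.statistic:.2f}, "
      f"p = {inter.p_value:.3f}")
print("\nThe declining contrasts mirror the simulated monthly decline; the")
print("interaction test is expectedly compatible with the (weak) simulated")
print("arm-by-time structure.")
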