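"""Train resampled leave-one-site-out age regressors and report performance.

Each site is held out in turn; the remaining sites' subjects are randomly
under-sampled to 80% N times and one feed-forward net is trained per round.
Prints MAE (years) and the age-prediction correlation R, overall and per
held-out site — sites whose age range is poorly covered by the others
degrade, which is the generalisation failure the design probes.
"""

from explainstab import (
    GeneratorConfig,
    ResamplingPlan,
    generate_cohort,
    run_resampled_loso,
    small_model_config,
)

cohort, _ = generate_cohort(GeneratorConfig(seed=1))
plan = ResamplingPlan(n_rounds=5, subsample_fraction=0.8, base_seed=1)
model_cfg = small_model_config(seed=1, max_epochs=120, early_stop_patience=12)

report, registry = run_resampled_loso(cohort, model_cfg, plan, keep_models=False)

print(f"overall MAE = {report.overall_mae:.2f} years "
      f"(mean over {plan.n_rounds}-round averaged predictions)")
print(f"overall R   = {report.overall_r:.2f} (chronological vs predicted age)")
print("per held-out site:")
for site, m in report.per_site_mae.items():
    print(f"  {site}: MAE {m:.2f} years, R {report.per_site_r[site]:.2f}")
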