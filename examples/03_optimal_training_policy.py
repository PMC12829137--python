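"""How should the WN threshold be updated to train fastest?

The model predicts learning is fastest when explorations trigger WN with
probability 1/2 (for any symmetric exploration density). The analytic
optimum is computed first; then matched synthetic birds are trained under
three threshold policies and their daily pitch improvements compared.
"""

from scipy import stats

from latentrl import (
    LearnerParams,
    SimulationConfig,
    ThresholdPolicy,
    compare_policies,
    default_repertoire,
    optimal_hit_probability,
)

q = optimal_hit_probability(stats.norm(), grid_resolution=1e-3)
print(f"optimal WN (hit) probability for Gaussian exploration: {q:.3f}")

cfg = SimulationConfig(rep=default_repertoire(),
                       learner=LearnerParams(alpha=0.003, delta=3e-4,
                                             sigma_eps2=100.0,
                                             sigma_eta2=0.01),
                       n_baseline_days=2, n_feedback_days=6, seed=42)
policies = {
    "running median (hit rate 1/2)": ThresholdPolicy("running_median",
                                                     window=20),
    "daily median": ThresholdPolicy("daily_quantile", q=0.5),
    "daily 80th percentile": ThresholdPolicy("daily_quantile", q=0.8),
}
tab = compare_policies(cfg, policies, n_birds=12)
print("\nmean daily pitch improvement (Hz/day, 12 matched birds):")
for name, grp in tab.groupby("policy"):
    print(f"  {name:32s} {grp['daily_improvement_hz'].mean():.2f}")
print("\nthe continuously tracking median realizes the 1/2 optimum; "
      "the 80th-percentile policy trains slower.")
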