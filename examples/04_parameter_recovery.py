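"""Small parameter-recovery experiment.

Simulates and refits the Domain x Target model 25 times at a reduced
cohort, then reports bias, RMSE and empirical 95% CI coverage for the
planted coefficients.  Scale `replicates` up for publication-grade checks.
"""

from parcelgrowth.simulate import recovery_experiment, reduced_recovery_config

config, spec = reduced_recovery_config(seed=0)
rep = recovery_experiment(config, spec, replicates=25, seed=42)

tab = rep["per_coefficient"]
planted = tab[tab["truth"] != 0]
print(f"{rep['n_ok']}/{rep['n_replicates']} replicates fitted")
print("\nplanted coefficients:")
print(planted[["truth", "mean_est", "bias", "rmse", "coverage"]].round(4))
print(f"\npooled 95% CI coverage: {rep['pooled_coverage']:.3f} "
      f"(+/- {rep['pooled_coverage_mcse']:.3f} MCSE)")
# Bias within a couple of Monte-Carlo SEs of zero and coverage near 0.95
# indicate the estimator and its Satterthwaite intervals are calibrated.
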