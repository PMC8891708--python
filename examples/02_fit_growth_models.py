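"""Fit and compare the two growth models on a synthetic cohort.

Simulates a desk-scale accelerated cohort from the Domain x Target model
with a planted self-salience effect, fits both growth models with
intercept+age random blocks, and reports the AIC comparison and the
hypothesis ledger.
"""

from parcelgrowth import AnalysisConfig, RandomEffectsBlock, run_growth_analysis
from parcelgrowth.simulate import reduced_recovery_config, simulate_observations

config, spec = reduced_recovery_config(seed=7)
obs = simulate_observations(config, spec)
print(f"simulated {len(obs)} observations: "
      f"{obs['participant_id'].nunique()} participants x "
      f"{obs['parcel_id'].nunique()} parcels x 4 conditions")

blocks = (RandomEffectsBlock("participant", [(), ("age",)], "full"),
          RandomEffectsBlock("parcel", [(), ("age",)], "full"))
res = run_growth_analysis(obs, AnalysisConfig(random_blocks_model1=blocks,
                                              random_blocks_model2=blocks))

c = res.comparison
print(f"\nAIC (ML refits): Domain model {c.aic_a:.1f}  "
      f"Domain x Target model {c.aic_b:.1f}  (delta {c.delta_aic:+.1f})")
print("selected:", "Domain x Target" if c.selected == "b" else "Domain")
# At this desk-scale cohort (30 parcels, 6 of them self) the planted Target
# effects buy roughly as much likelihood as the 18 extra coefficients cost,
# so the AIC decision is borderline; at the full design (352 parcels, 135
# sessions) the same effects dominate the penalty.

focal = ["gamma_601.self", "gamma_801.self", "gamma_901.self"]
print("\nfocal self-parcel coefficients (truth planted at 0.255, 0.026, -0.011):")
print(res.fit2.coef_table().loc[focal, ["b", "se", "t", "df", "p"]].round(4))

print("\nhypothesis ledger (Bonferroni-adjusted):")
print(res.ledger[["hypothesis", "test", "estimate", "p", "adjusted_p"]]
      .round(4).to_string(index=False))
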