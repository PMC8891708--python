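# parcelgrowth

Cross-classified growth-curve modelling of parcellated longitudinal
task-fMRI data.

Developmental neuroimaging studies often reduce whole-brain contrast
images to parcel-level summaries and ask how the response in functionally
labelled parcel sets (e.g. *self*- and *social*-processing regions versus
*control* regions) changes across adolescence and task conditions.  This
package implements that analysis chain end to end, for researchers who
want a tested, scriptable alternative to ad-hoc pipelines:

* **Extraction** — per-parcel means from NIfTI contrast images against an
  integer-labelled atlas (no implicit resampling), within-parcel
  standardization (divide by the parcel's SD across sessions), and a 3-SD
  grand-mean outlier screen.
* **Growth models** — polynomial (age, age²) mixed-effects models with
  *crossed* random effects for participants and parcels, categorical
  moderators (Domain × Target task design, parcel category), estimated by
  profiled ML/REML from scratch on sparse penalized normal equations.
* **Inference** — Wald coefficient and contrast tests with Satterthwaite
  degrees of freedom, AIC model comparison with a 2-point rule, Bonferroni
  families, simple slopes at a reference age, and predicted developmental
  trajectories (optionally per parcel via BLUPs).
* **Synthetic cohorts** — an accelerated 3-wave cohort generator and
  simulate–fit recovery experiments, so every stage runs at desk scale
  without any data download.

The model, for observation *i* of participant *j* in parcel *k*:

    Y_ijk = Σ_t β_tjk x_t(i) + ε_ijk
    β_tjk = γ_t00 + γ_t01 Label_k + u_tj + u_tk

with growth terms x_t built from {1, age−13, (age−13)², Domain, Target}
(factors coded −0.5/+0.5), parcel labels treatment-coded against control,
u_j ~ N(0, Ψ_participant), u_k ~ N(0, Ψ_parcel), ε ~ N(0, σ²).  The
engine reproduces lme4/lmerTest results to numerical precision on shared
test problems (see `tests/test_lmm.py`).

## Worked example

```python
from parcelgrowth import AnalysisConfig, RandomEffectsBlock, run_growth_analysis
from parcelgrowth.simulate import reduced_recovery_config, simulate_observations

config, spec = reduced_recovery_config(seed=7)
obs = simulate_observations(config, spec)      # 8760 rows: 40 participants,
                                               # 30 parcels, 4 conditions
blocks = (RandomEffectsBlock("participant", [(), ("age",)], "full"),
          RandomEffectsBlock("parcel", [(), ("age",)], "full"))
res = run_growth_analysis(obs, AnalysisConfig(random_blocks_model1=blocks,
                                              random_blocks_model2=blocks))
print(res.comparison.delta_aic)
print(res.fit2.coef_table().loc["gamma_601.self"].round(4))
```

prints (seed 7):

```
4.0999...
b     0.2393
se    0.0849
t     2.8199
df    8611.4566
p     0.0048
```

The planted Target × Label(self) effect of 0.255 is recovered as 0.239 ±
0.085 and is clearly detected (p ≈ .005).  The AIC difference between the
Domain and Domain × Target models is borderline (+4.1) at this reduced
cohort — the planted condition effects buy about as much likelihood as
the 18 extra coefficients cost; at the full study geometry (352 parcels,
135 sessions) the same effects dominate the penalty.

The `examples/` directory has one short script per capability:
extraction from synthetic NIfTI volumes, model fitting and comparison,
simple-slope reconstruction from a published coefficient table, and a
parameter-recovery experiment.  A thin CLI (`parcelgrowth extract|simulate|fit`)
wraps the same functions for batch use.

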