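# Methods

## The model

`parcelgrowth` analyses longitudinal task-fMRI data that have been reduced
to parcel-level contrast estimates: one value per participant × wave ×
task condition × brain parcel.  The task design crosses **Domain**
(Academic vs Social stimulus content) with **Target** (evaluating Self vs
an Other), and every parcel carries a category label — *self*, *social*,
or *control* — describing which functional system it belongs to.

The response is modelled with a cross-classified polynomial growth model.
For observation *i* of participant *j* in parcel *k*:

```
Y_ijk = sum_t beta_tjk * x_t(i) + e_ijk,       e_ijk ~ N(0, sigma^2)
```

where the within-cell growth terms `x_t` are products over
{1, age_c, age_c^2, Domain, Target} (age_c = age − 13 years; factors coded
−0.5/+0.5 so the intercept is the cell average).  Each coefficient
equation decomposes into a fixed part moderated by the parcel category
(treatment-coded, control as reference, so the base coefficient describes
control parcels) plus participant and parcel deviations:

```
beta_tjk = gamma_t00 + gamma_t01.self * I(self) + gamma_t01.soc * I(social)
           + u_tj + u_tk
```

Two canonical specifications are built in:

* **Domain model** — 6 growth terms (intercept, age, age², domain,
  age×domain, age²×domain) × 3 label levels = 18 fixed effects;
  participant deviations on {1, age, domain} (full 3×3 covariance, 6
  parameters) and parcel deviations on {1, age, age², domain} (10
  parameters); with the residual variance, 35 parameters.
* **Domain × Target model** — all 12 growth terms × 3 labels = 36 fixed
  effects; participant deviations on the 8 coefficient equations that
  carry participant terms (36 covariance parameters) and parcel deviations
  on all 12 (78 parameters); 151 parameters in total.

Both random structures are configurable: `GrowthModelSpec.with_random_blocks`
swaps in any subset of terms per grouping factor, with full or diagonal
covariance.  Desk-scale work (tests, examples, recovery experiments) uses
intercept + age blocks for both factors, because the canonical structures
are identified only at the full study size (352 parcels, 135 sessions).

## Estimation

Estimation follows the penalized least-squares formulation of Gaussian
mixed models.  Each random block has a relative Cholesky factor
Lambda_b(theta) scaled by the residual SD; for any theta, the fixed
effects and sigma² are profiled out analytically, leaving the profiled
(restricted) deviance as a function of theta alone.  A single Cholesky
factorization of the penalized normal equations

```
[ Lam' Z'Z Lam + I   Lam' Z'X ]
[ X'Z Lam            X'X      ]
```

yields both log-determinants the deviance needs, the spherical conditional
modes, the GLS fixed effects and the penalized residual sum of squares.
Cross-products (Z'Z, Z'X, X'X, ...) are assembled once per design with
sparse matrices; the per-iteration factorization is dense LAPACK, which is
the right trade-off at the problem sizes this package targets (a few
hundred to a few thousand random coefficients).

### Numerical choices

* **theta parameterization.** The diagonal of each relative Cholesky
  factor is optimized on the *linear* scale with a lower bound of zero;
  off-diagonals are free.  A log-scale diagonal was tried first and
  rejected: its flat tail near zero variance stalls finite-difference
  optimizers far from the optimum, while the linear scale represents
  boundary (singular) fits exactly.
* **Optimizer.** Derivative-free Powell search (scipy), xtol 1e-8, ftol
  1e-10, matching the spirit of the BOBYQA default in the standard mixed-
  model software.  Finite-difference quasi-Newton was less reliable near
  the variance boundary.  Estimation is fully deterministic; no stochastic
  restarts are used.
* **Singular fits** (any relative scale < 1e-3) are flagged, not raised:
  boundary fits are information the analyst needs when pruning random
  structures for convergence.
* **Starting values**: unit relative scales, zero correlations.
* **Degenerate inputs**: a rank-deficient fixed design raises an error
  naming the collinear columns; a grouping factor with one level raises;
  a penalized RSS below 1e-12 is floored (exact interpolation).

### Inference

Coefficient and contrast tests are Wald t statistics.  Degrees of freedom
use the Satterthwaite approximation: df = 2·Var(c'g)² / Var[Var(c'g)],
with the denominator from the delta method — the gradient of
c'·Cov(gamma)·c with respect to the variance parameters (theta and log
sigma²), against twice the inverse curvature of the deviance at the
optimum (central finite differences throughout).  Verified against
`lmerTest` on crossed designs: agreement to ≈4 significant digits, and
exact classical limits (n−p for OLS, g−1 for the grand mean of a balanced
one-way random-intercept layout).  If the curvature is not positive
definite the df falls back to infinity (normal approximation) with a
warning.

Model comparison is by AIC with a 2-point threshold: the richer model is
selected only if it lowers AIC by ≥ 2; ties go to the model with fewer
parameters.  Reported estimates default to REML; AIC comparison defaults
to ML refits (started from the REML solution), because comparing REML
deviances across models with different fixed effects is not meaningful.
Both deviances are emitted, and a switch selects REML-AIC for users who
want to mirror software that reports it.

### Simple slopes and families

The instantaneous age slope of a condition contrast (e.g. Self − Other
for Social stimuli in self parcels) at age *a* places weight 1 on the
Age×factor terms, the conditioning code (±0.5) on the Age×factor×other
terms, and 2(a−13) on the corresponding Age² terms — base plus
label-moderation coefficients summed within the parcel category.  The
companion curvature contrast is the Age² coefficient of the same
difference.  Multiple-comparison families are Bonferroni: m = 2 for the
two salience hypotheses (H1 social, H2 self), m = 4 for each of the
targeted interaction hypotheses (H3A, H3B), which have two coefficients
plus a slope and a curvature contrast each.

## Extraction and harmonization

Parcel means are arithmetic means of image voxels inside each integer
atlas label (background 0 excluded); non-finite voxels are dropped from
numerator and denominator.  Image and atlas must share the voxel grid
exactly (shape, spacing, affine); the package never resamples.  Values are
then divided by the within-parcel sample SD (n−1) pooled over all sessions
and conditions — no mean-centring, so condition contrasts survive — and
observations more than z = 3 grand SDs from the grand mean of the
standardized values are excluded, with the grand moments computed once
over all observations.  A per-cell SD divisor (parcel × wave × condition,
across participants) is available as an option; pooling is the default
because it preserves the condition contrasts the growth models estimate,
and the upstream literature does not specify the cell structure.
Standardizing over all waves jointly (rather than per wave) is likewise
the default reading.

## The synthetic cohort

The generator emulates an accelerated 3-wave adolescent cohort: waves of
57/44/34 sessions from 74 participants (35/17/22 with 1/2/3 waves), wave
ages drawn from truncated normals with means 10.08/13.06/16.33 and SDs
0.32/0.33/0.46 years (truncation 9–17.5).  Within a participant,
later-wave ages are the first age plus ~N(3.0, 0.3) years per wave step —
longitudinally linked, not independent draws.  Wave attendance sets are
allocated deterministically (3-wave participants first, then 2-wave pairs
to the fullest waves, then singles), so any feasible design is filled
exactly and infeasible ones raise.  Responses are generated from the
growth model read generatively: fixed surface + multivariate-normal
participant and parcel deviations + i.i.d. Gaussian residual.  Parcel
categories default to the study's 19/44/289 split.

What it does *not* emulate: spatial structure within and between parcels,
temporal autocorrelation, motion artefacts, scanner drift, sex/puberty
covariates, and any misspecification of the polynomial form.  Passing
recovery tests therefore demonstrates that the estimator is calibrated
for data generated by its own model class, not that the model is right
for real brains.

### Recovery defaults

The reduced recovery design uses 40 participants (19/9/12 retention, 73
sessions), 30 parcels (6 self / 9 social / 15 control), 4 conditions —
8,760 rows per replicate — with intercept+age random blocks for both
factors (participant variances 0.040/0.004, parcel 0.090/0.006, residual
0.8, all in squared standardized-BOLD units, chosen to sit in the range
typical of parcel-level contrast estimates after harmonization).  Planted
fixed effects are the published headline values (e.g. Target×Label(self)
= 0.255).  These sizes keep one simulate-and-fit cycle under a second, so
hundreds of replicates run in minutes.

In the recovery acceptance checks, the planted headline coefficient and
the pooled CI coverage are tested at a plain 2-MCSE band (coverage MCSE is
clustered by replicate, since the 36 coefficients within a replicate share
data).  The simultaneous per-coefficient bias check across all 36 fixed
effects uses a Šidák-adjusted band (family α = 0.05, z ≈ 3.2): at a plain
2-sigma band, 36 correlated z tests would fail somewhere ≳15% of the time
even for a perfectly calibrated estimator.

## Known limitations

* The canonical 151-parameter random structure is fittable in principle
  but slow with derivative-free optimization (hundreds of covariance
  parameters); it is intended for full-scale data, and reproducing the
  published full-data coefficient table additionally requires downloading
  the study's deposited parcel-level dataset — an optional external check,
  not part of the test suite.
* No Kenward–Roger small-sample correction; Satterthwaite only.
* Gaussian responses and i.i.d. residuals only; no autocorrelation or
  heteroscedasticity, no generalized or Bayesian variants.
* The extraction stage requires pre-aligned inputs; registration,
  smoothing and first-level GLMs belong upstream.
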