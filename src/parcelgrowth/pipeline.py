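"""End-to-end growth-curve analysis of parcel-level observations.

Builds the two published model specifications (Domain, and Domain x
Target), fits them, compares them by AIC, assembles the hypothesis ledger
with Bonferroni-adjusted p values, probes interactions with simple slopes
at a given age, and predicts developmental trajectories over an age grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as dz
from .design import (GrowthModelSpec, GROWTH_TERMS, RandomEffectsBlock,
                     build_design, gamma_name, term_label)
from .lmm import LMMFit, ContrastResult, compare_models, fit_lmm, wald_contrast

__all__ = [
    "make_model1_spec", "make_model2_spec", "AnalysisConfig",
    "run_growth_analysis", "simple_slope", "quadratic_contrast",
    "bonferroni_adjust", "predict_trajectories", "hypothesis_ledger",
]

MODEL1_TERMS = GROWTH_TERMS[:6]
MODEL2_TERMS = GROWTH_TERMS

#: Participant coefficient equations carrying deviations in the
#: Domain x Target model: intercept, age, domain, age*domain, target,
#: domain*target, age*target, age*domain*target.
MODEL2_PARTICIPANT_TERMS = (
    (), ("age",), ("domain",), ("age", "domain"),
    ("target",), ("domain", "target"), ("age", "target"),
    ("age", "domain", "target"),
)


def make_model1_spec() -> GrowthModelSpec:
    """Domain growth model: 6 base terms x 3 label levels = 18 fixed effects.

    Random structure: participant {intercept, age, domain} and parcel
    {intercept, age, age^2, domain}, both full covariance — 35 parameters
    in total including the residual variance.
    """
    return GrowthModelSpec(
        name="Model 1 - Domain",
        base_terms=MODEL1_TERMS,
        random_blocks=(
            RandomEffectsBlock("participant", ((), ("age",), ("domain",)), "full"),
            RandomEffectsBlock("parcel", ((), ("age",), ("age2",), ("domain",)), "full"),
        ))


def make_model2_spec() -> GrowthModelSpec:
    """Domain x Target growth model: 12 base terms x 3 labels = 36 fixed effects.

    Random structure: participant deviations on 8 coefficient equations and
    parcel deviations on all 12, full covariance each — 151 parameters in
    total including the residual variance.
    """
    return GrowthModelSpec(
        name="Model 2 - Domain x Target",
        base_terms=MODEL2_TERMS,
        random_blocks=(
            RandomEffectsBlock("participant", MODEL2_PARTICIPANT_TERMS, "full"),
            RandomEffectsBlock("parcel", MODEL2_TERMS, "full"),
        ))


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni correction: min(1, m*p)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ValueError(f"m must be an integer >= 1, got {m!r}")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# simple slopes


def _slope_weights(fit_names, factor: str, other_factor: str,
                   conditioning_code: float, parcel_label: str,
                   age: float) -> dict:
    """Weights for d/d(age) of the factor contrast at a given age.

    The contrast is the difference between the +0.5 and -0.5 codings of
    ``factor`` (Self-Other or Social-Academic), within ``parcel_label``,
    with ``other_factor`` held at ``conditioning_code``.  Because the
    factor codes differ by 1, the derivative places unit weight on the
    Age x factor terms, the conditioning code on Age x factor x other
    terms, and 2*(age-13) on the corresponding Age^2 terms.
    """
    a = age - dz.AGE_CENTER
    w: dict[str, float] = {}

    def add(term, weight):
        nm = gamma_name(term, "control")
        w[nm] = w.get(nm, 0.0) + weight
        if parcel_label != "control":
            nm_l = gamma_name(term, parcel_label)
            w[nm_l] = w.get(nm_l, 0.0) + weight

    add(("age", factor), 1.0)
    add(tuple(sorted(("age", factor, other_factor),
                     key=["age", "domain", "target"].index)), conditioning_code)
    add(("age2", factor), 2.0 * a)
    add(tuple(sorted(("age2", factor, other_factor),
                     key=["age2", "domain", "target"].index)), 2.0 * a * conditioning_code)
    missing = [k for k in w if k not in fit_names]
    if missing:
        raise ValueError(f"fit lacks coefficients needed for the slope: {missing}")
    return w


def simple_slope(fit: LMMFit, contrast_factor: str, conditioning_code: float,
                 parcel_label: str, age: float = 13.0) -> ContrastResult:
    """Instantaneous age slope of a condition contrast at a given age.

    Parameters
    ----------
    contrast_factor : {'target_diff', 'domain_diff'}
        'target_diff' is the Self - Other difference; 'domain_diff' the
        Social - Academic difference.
    conditioning_code : float
        Code (+0.5/-0.5) at which the other factor is held.
    parcel_label : {'control', 'self', 'social'}
    age : years
    """
    if parcel_label not in dz.PARCEL_LABELS:
        raise ValueError(f"unknown parcel label {parcel_label!r}; "
                         f"valid: {list(dz.PARCEL_LABELS)}")
    factor, other = _factor_pair(contrast_factor)
    w = _slope_weights(set(fit.gamma.index), factor, other,
                       conditioning_code, parcel_label, age)
    return wald_contrast(fit, w)


def quadratic_contrast(fit: LMMFit, contrast_factor: str, conditioning_code: float,
                       parcel_label: str) -> ContrastResult:
    """Quadratic-age coefficient of a condition contrast (curvature term)."""
    if parcel_label not in dz.PARCEL_LABELS:
        raise ValueError(f"unknown parcel label {parcel_label!r}; "
                         f"valid: {list(dz.PARCEL_LABELS)}")
    factor, other = _factor_pair(contrast_factor)
    w: dict[str, float] = {}

    def add(term, weight):
        nm = gamma_name(term, "control")
        w[nm] = w.get(nm, 0.0) + weight
        if parcel_label != "control":
            w[gamma_name(term, parcel_label)] = weight

    add(("age2", factor), 1.0)
    add(tuple(sorted(("age2", factor, other),
                     key=["age2", "domain", "target"].index)), conditioning_code)
    return wald_contrast(fit, w)


def _factor_pair(contrast_factor: str) -> tuple[str, str]:
    if contrast_factor == "target_diff":
        return "target", "domain"
    if contrast_factor == "domain_diff":
        return "domain", "target"
    raise ValueError("contrast_factor must be 'target_diff' or 'domain_diff'")


# ---------------------------------------------------------------------------
# trajectories


def predict_trajectories(fit: LMMFit, age_grid=None, cells=None,
                         blups: bool = False,
                         age_range=(9.0, 17.0)) -> pd.DataFrame:
    """Fixed-effect predicted means per (label, domain, target, age).

    With ``blups=True`` adds per-parcel predicted curves (fixed-effect
    surface plus each parcel's predicted deviations).  Ages outside
    ``age_range`` warn but still predict.
    """
    import warnings

    if age_grid is None:
        age_grid = np.arange(9.0, 17.0 + 1e-9, 0.1)
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.min() < age_range[0] or age_grid.max() > age_range[1]:
        warnings.warn("age grid extends beyond the observed age range; "
                      "predictions are extrapolations")
    if cells is None:
        cells = [(lab, d, t) for lab in dz.PARCEL_LABELS
                 for d in ("Academic", "Social") for t in ("Other", "Self")]

    names = list(fit.gamma.index)
    g = fit.gamma
    rows = []
    for lab, d, t in cells:
        dcode, tcode = dz.code_condition(d, t)
        for age in age_grid:
            a = age - dz.AGE_CENTER
            vals = {"age": a, "age2": a * a, "domain": dcode, "target": tcode}
            mu = 0.0
            for term in GROWTH_TERMS:
                nm = gamma_name(term, "control")
                if nm not in names:
                    continue
                x = float(np.prod([vals[tok] for tok in term])) if term else 1.0
                mu += g[nm] * x
                if lab != "control":
                    nm_l = gamma_name(term, lab)
                    if nm_l in names:
                        mu += g[nm_l] * x
            rows.append((lab, d, t, age, mu))
    out = pd.DataFrame(rows, columns=["parcel_label", "domain", "target",
                                      "age", "predicted"])
    if blups:
        out = _add_parcel_curves(fit, out)
    return out


def _add_parcel_curves(fit: LMMFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Attach per-parcel predicted deviations from the parcel BLUPs."""
    blk = next((b for b in fit.blocks if b.spec.grouping == "parcel"), None)
    if blk is None:
        return grid
    recs = []
    for _, row in grid.iterrows():
        a = row["age"] - dz.AGE_CENTER
        dcode, tcode = dz.code_condition(row["domain"], row["target"])
        vals = {"age": a, "age2": a * a, "domain": dcode, "target": tcode}
        x = np.array([float(np.prod([vals[tok] for tok in t])) if t else 1.0
                      for t in blk.spec.terms])
        dev = blk.blups.to_numpy() @ x
        for pid, d in zip(blk.levels, dev):
            recs.append((pid, row["parcel_label"], row["domain"], row["target"],
                         row["age"], row["predicted"] + d))
    per_parcel = pd.DataFrame(recs, columns=["parcel_id", "parcel_label", "domain",
                                             "target", "age", "predicted_parcel"])
    return grid.merge(per_parcel, on=["parcel_label", "domain", "target", "age"])


# ---------------------------------------------------------------------------
# hypothesis ledger


def hypothesis_ledger(fit: LMMFit) -> pd.DataFrame:
    """The pre-registered coefficient and slope tests with Bonferroni families.

    H1 (social salience): Age x Domain x Label(social) and Age^2 x Domain x
    Label(social), family of 2.  H2 (self salience): Age x Target x
    Label(self) and Age^2 x Target x Label(self), family of 2.  H3A/H3B:
    the four-way coefficients plus the corresponding simple-slope and
    curvature contrasts at age 13, families of 4.
    """
    ct = fit.coef_table()

    def coef_row(hid, name, m):
        r = ct.loc[name]
        return dict(hypothesis=hid, test=name, kind="coefficient",
                    estimate=r["b"], se=r["se"], t=r["t"], df=r["df"],
                    p=r["p"], m=m, adjusted_p=bonferroni_adjust(float(r["p"]), m))

    def contrast_row(hid, label, cr: ContrastResult, m):
        return dict(hypothesis=hid, test=label, kind="contrast",
                    estimate=cr.estimate, se=cr.se, t=cr.t, df=cr.df,
                    p=cr.p, m=m, adjusted_p=bonferroni_adjust(float(cr.p), m))

    rows = [
        coef_row("H1", "gamma_401.soc", 2),
        coef_row("H1", "gamma_501.soc", 2),
        coef_row("H2", "gamma_801.self", 2),
        coef_row("H2", "gamma_901.self", 2),
        coef_row("H3A", "gamma_1001.soc", 4),
        coef_row("H3A", "gamma_1101.soc", 4),
        contrast_row("H3A", "slope: Self (Social-Academic), social parcels, age 13",
                     simple_slope(fit, "domain_diff", +0.5, "social", 13.0), 4),
        contrast_row("H3A", "curvature: Self (Social-Academic), social parcels",
                     quadratic_contrast(fit, "domain_diff", +0.5, "social"), 4),
        coef_row("H3B", "gamma_1001.self", 4),
        coef_row("H3B", "gamma_1101.self", 4),
        contrast_row("H3B", "slope: Social (Self-Other), self parcels, age 13",
                     simple_slope(fit, "target_diff", +0.5, "self", 13.0), 4),
        contrast_row("H3B", "curvature: Social (Self-Other), self parcels",
                     quadratic_contrast(fit, "target_diff", +0.5, "self"), 4),
    ]
    led = pd.DataFrame(rows)
    led["decision"] = np.where(led["adjusted_p"] < 0.05,
                               "significant (adj. p < .05)", "not significant")
    return led


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisConfig:
    """Switches for a full analysis run."""

    objective: str = "REML"          # objective for reported estimates
    aic_objective: str = "ML"        # objective refit for AIC comparison
    random_blocks_model1: tuple | None = None   # override canonical structure
    random_blocks_model2: tuple | None = None
    age_grid: np.ndarray | None = None
    blup_trajectories: bool = False
    seed: int = 0


@dataclass
class AnalysisResults:
    fit1: LMMFit
    fit2: LMMFit
    comparison: object
    coef_table: pd.DataFrame
    ledger: pd.DataFrame
    trajectories: pd.DataFrame
    manifest: dict
    fit1_ml: LMMFit | None = None
    fit2_ml: LMMFit | None = None


def run_growth_analysis(obs: pd.DataFrame, config: AnalysisConfig | None = None) -> AnalysisResults:
    """Fit both growth models, compare them, and assemble all reports.

    Estimates are reported from the ``config.objective`` fits; the AIC
    comparison uses ``config.aic_objective`` refits (both deviances are kept
    in the manifest).  Random structures default to the canonical ones and
    may be overridden for reduced-scale work.
    """
    config = config or AnalysisConfig()
    obs = dz.validate_observations(obs) if "age_c" not in obs.columns else obs
    for col, want in (("domain", set(dz.DOMAIN_CODE)), ("target", set(dz.TARGET_CODE))):
        present = set(obs[col].unique())
        if present != want:
            raise ValueError(f"{col} must have both levels present, found {sorted(present)}")

    spec1, spec2 = make_model1_spec(), make_model2_spec()
    if config.random_blocks_model1 is not None:
        spec1 = spec1.with_random_blocks(config.random_blocks_model1)
    if config.random_blocks_model2 is not None:
        spec2 = spec2.with_random_blocks(config.random_blocks_model2)

    dm1, dm2 = build_design(obs, spec1), build_design(obs, spec2)
    fit1 = fit_lmm(dm1, spec=spec1, objective=config.objective)
    fit2 = fit_lmm(dm2, spec=spec2, objective=config.objective)

    fit1_ml = fit2_ml = None
    if config.aic_objective == config.objective:
        comparison = compare_models(fit1, fit2)
    else:
        fit1_ml = fit_lmm(dm1, spec=spec1, objective=config.aic_objective,
                          theta0=fit1.theta)
        fit2_ml = fit_lmm(dm2, spec=spec2, objective=config.aic_objective,
                          theta0=fit2.theta)
        comparison = compare_models(fit1_ml, fit2_ml)

    best = fit2 if comparison.selected == "b" else fit1
    coef_table = best.coef_table()
    ledger = hypothesis_ledger(fit2)
    trajectories = predict_trajectories(best, age_grid=config.age_grid,
                                        blups=config.blup_trajectories)
    manifest = {
        "objective": config.objective,
        "aic_objective": config.aic_objective,
        "n_obs": int(len(obs)),
        "model1": fit1.to_dict(), "model2": fit2.to_dict(),
        "comparison": comparison.to_dict(),
        "selected": "model2" if comparison.selected == "b" else "model1",
        "seed": config.seed,
    }
    return AnalysisResults(fit1=fit1, fit2=fit2, comparison=comparison,
                           coef_table=coef_table, ledger=ledger,
                           trajectories=trajectories, manifest=manifest,
                           fit1_ml=fit1_ml, fit2_ml=fit2_ml)


def write_results(results: AnalysisResults, outdir) -> None:
    """Write coefficient table, comparison, ledger and trajectories to disk."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.coef_table.to_csv(out / "coefficients.tsv", sep="\t")
    results.ledger.to_csv(out / "hypothesis_ledger.tsv", sep="\t", index=False)
    results.trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False)
    with open(out / "comparison.json", "w", encoding="utf-8") as fh:
        json.dump(results.comparison.to_dict(), fh, indent=2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(results.manifest, fh, indent=2)
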