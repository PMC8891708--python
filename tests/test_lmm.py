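"""Mixed-model engine: deviance oracle agreement, closed-form variance
components, Satterthwaite df in classical limits, contrasts, AIC rules."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

import parcelgrowth as pg
from parcelgrowth.design import RandomEffectsBlock, build_design
from parcelgrowth.lmm import (compare_models, fit_lmm, profiled_deviance,
                              satterthwaite_df, wald_contrast)
from conftest import dense_deviance, make_crossed_obs


def simple_obs(rows):
    obs = pd.DataFrame(rows, columns=["participant_id", "wave", "age", "domain",
                                      "target", "parcel_id", "parcel_label", "bold"])
    return pg.validate_observations(obs)


class TestProfiledDeviance:
    @pytest.mark.parametrize("objective", ["ML", "REML"])
    def test_matches_dense_oracle_random_battery(self, objective):
        """Sparse profiled deviance vs direct marginal-likelihood evaluation
        on randomized crossed designs up to 500 observations."""
        rng = np.random.default_rng(11)
        configs = [
            dict(n_participants=6, n_parcels=4, n_waves=1,
                 blocks=[RandomEffectsBlock("participant", [()], "full"),
                         RandomEffectsBlock("parcel", [()], "full")]),
            dict(n_participants=5, n_parcels=3, n_waves=2,
                 blocks=[RandomEffectsBlock("participant", [(), ("age",)], "full"),
                         RandomEffectsBlock("parcel", [()], "full")]),
            dict(n_participants=4, n_parcels=3, n_waves=2,
                 blocks=[RandomEffectsBlock("participant", [(), ("domain",)], "diagonal"),
                         RandomEffectsBlock("parcel", [(), ("age",)], "full")]),
        ]
        for ci, cfg in enumerate(configs):
            obs = make_crossed_obs(cfg["n_participants"], cfg["n_parcels"],
                                   cfg["n_waves"], seed=100 + ci)
            assert len(obs) <= 500
            spec = pg.GrowthModelSpec(
                "battery", [(), ("age",), ("domain",), ("target",)],
                random_blocks=tuple(cfg["blocks"]), label_moderation=False)
            dm = build_design(obs, spec)
            y = obs["bold"].to_numpy()
            n_theta = sum(b.n_cov_params for b in cfg["blocks"])
            for _ in range(4):
                theta = rng.normal(0, 0.6, n_theta)
                ours = profiled_deviance(theta, dm, y, objective)
                oracle = dense_deviance(theta, dm, y, objective)
                assert ours == pytest.approx(oracle, abs=1e-6)

    def test_zero_variance_limit_equals_ols(self, crossed_obs, intercepts_spec):
        dm = build_design(crossed_obs, intercepts_spec)
        y = crossed_obs["bold"].to_numpy()
        theta = np.array([0.0, 0.0])  # zero relative scales -> no random variance
        dev = profiled_deviance(theta, dm, y, "ML")
        # OLS deviance on the same fixed design
        n = len(y)
        beta, *_ = np.linalg.lstsq(dm.X, y, rcond=None)
        rss = float(np.sum((y - dm.X @ beta) ** 2))
        dev_ols = n * (1 + np.log(2 * np.pi * rss / n))
        assert dev == pytest.approx(dev_ols, abs=1e-6)

    def test_duplicated_observations_match_oracle(self, crossed_obs, intercepts_spec):
        dup = crossed_obs.copy()
        dup["wave"] = dup["wave"] + 10     # distinct design cells, same values
        both = pg.validate_observations(pd.concat([crossed_obs, dup], ignore_index=True))
        dm = build_design(both, intercepts_spec)
        y = both["bold"].to_numpy()
        theta = np.array([0.3, -0.2])
        assert profiled_deviance(theta, dm, y, "REML") == pytest.approx(
            dense_deviance(theta, dm, y, "REML"), abs=1e-6)

    def test_rank_deficient_design_names_columns(self, crossed_obs):
        spec = pg.GrowthModelSpec("bad", [(), ("age",), ("age",)],
                                  label_moderation=False)
        dm = build_design(crossed_obs, spec)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(dm)


class TestFit:
    def test_noise_free_fixed_surface_interpolated(self, crossed_obs, intercepts_spec):
        dm0 = build_design(crossed_obs, intercepts_spec)
        gamma = np.array([0.5, 0.1, -0.3, 0.2])
        obs = crossed_obs.copy()
        obs["bold"] = dm0.X @ gamma
        dm = build_design(obs, intercepts_spec)
        fit = fit_lmm(dm, objective="REML")
        assert np.allclose(fit.gamma.to_numpy(), gamma, atol=1e-8)
        assert fit.singular

    def test_oneway_reml_equals_anova_closed_form(self):
        rng = np.random.default_rng(7)
        g, n = 8, 6
        rows = []
        for j in range(g):
            b = rng.normal(0, 1.2)
            for i in range(n):
                rows.append((f"p{j}", i, 13.0, "Social", "Self", 1, "control",
                             2.0 + b + rng.normal(0, 0.7)))
        obs = simple_obs(rows)
        spec = pg.GrowthModelSpec(
            "oneway", [()],
            random_blocks=(RandomEffectsBlock("participant", [()], "full"),),
            label_moderation=False)
        fit = fit_lmm(build_design(obs, spec), objective="REML")
        y = obs["bold"].to_numpy().reshape(g, n)
        msb = n * ((y.mean(1) - y.mean()) ** 2).sum() / (g - 1)
        msw = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (g * (n - 1))
        assert fit.sigma2 == pytest.approx(msw, rel=1e-5)
        assert fit.blocks[0].psi[0, 0] == pytest.approx((msb - msw) / n, rel=1e-4)

    def test_ml_and_reml_gamma_coincide_on_balanced_design(self):
        rng = np.random.default_rng(9)
        rows = []
        for j in range(10):
            b = rng.normal(0, 1.0)
            for i in range(4):
                rows.append((f"p{j}", i, 13.0, "Social", "Self", 1, "control",
                             b + rng.normal()))
        obs = simple_obs(rows)
        spec = pg.GrowthModelSpec(
            "oneway", [()],
            random_blocks=(RandomEffectsBlock("participant", [()], "full"),),
            label_moderation=False)
        dm = build_design(obs, spec)
        f_ml = fit_lmm(dm, objective="ML")
        f_reml = fit_lmm(dm, objective="REML")
        assert f_ml.gamma.iloc[0] == pytest.approx(f_reml.gamma.iloc[0], abs=1e-7)
        assert f_ml.gamma.iloc[0] == pytest.approx(obs["bold"].mean(), abs=1e-7)

    def test_row_permutation_invariance(self, intercepts_spec):
        obs = make_crossed_obs(seed=21)
        rng = np.random.default_rng(0)
        perm = obs.sample(frac=1.0, random_state=5)
        f1 = fit_lmm(build_design(obs, intercepts_spec))
        f2 = fit_lmm(build_design(perm, intercepts_spec))
        assert np.allclose(f1.gamma.to_numpy(), f2.gamma.to_numpy(), atol=1e-6)

    def test_aic_identity(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        assert fit.aic == fit.deviance + 2 * fit.n_params

    def test_single_level_grouping_rejected(self, intercepts_spec):
        obs = make_crossed_obs(n_participants=1)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            fit_lmm(build_design(obs, intercepts_spec))

    def test_agreement_with_lme4_reference(self, tmp_path):
        """Independent cross-check of criterion, sigma^2 and fixed effects
        against the lme4 reference implementation on a small crossed set."""
        obs = make_crossed_obs(n_participants=8, n_parcels=5, n_waves=2, seed=42)
        spec = pg.GrowthModelSpec(
            "xcheck", [(), ("age",), ("domain",)],
            random_blocks=(RandomEffectsBlock("participant", [()], "full"),
                           RandomEffectsBlock("parcel", [()], "full")),
            label_moderation=False)
        fit = fit_lmm(build_design(obs, spec), objective="REML")
        tsv = tmp_path / "d.tsv"
        obs.to_csv(tsv, sep="\t", index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.delim("{tsv}")
            d$age_c <- d$age - 13
            d$dom <- ifelse(d$domain == "Social", 0.5, -0.5)
            m <- lmer(bold ~ 1 + age_c + dom + (1 | participant_id) + (1 | parcel_id),
                      data = d, REML = TRUE)
            cat(REMLcrit(m), sigma(m)^2, fixef(m), sep="\\n")
        """)
        rfile = tmp_path / "m.R"
        rfile.write_text(rscript)
        try:
            out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"reference lme4 fit unavailable: {exc}")
        crit, s2, b0, b_age, b_dom = map(float, out.stdout.split())
        assert fit.deviance == pytest.approx(crit, abs=1e-3)
        assert fit.sigma2 == pytest.approx(s2, rel=1e-4)
        assert fit.gamma["gamma_000"] == pytest.approx(b0, abs=1e-5)
        assert fit.gamma["gamma_100"] == pytest.approx(b_age, abs=1e-5)
        assert fit.gamma["gamma_300"] == pytest.approx(b_dom, abs=1e-5)


class TestSatterthwaite:
    def test_ols_two_group_df(self):
        rng = np.random.default_rng(3)
        rows = [(f"a{i}", 1, 13.0, "Social", "Self", 1, "control", rng.normal())
                for i in range(10)]
        rows += [(f"b{i}", 1, 13.0, "Academic", "Self", 1, "control", 1 + rng.normal())
                 for i in range(12)]
        obs = simple_obs(rows)
        spec = pg.GrowthModelSpec("two", [(), ("domain",)], label_moderation=False)
        fit = fit_lmm(build_design(obs, spec))
        assert satterthwaite_df(fit, {"gamma_300": 1.0}) == pytest.approx(20.0, abs=1e-3)

    def test_oneway_grand_mean_df_is_groups_minus_one(self):
        rng = np.random.default_rng(5)
        g, n = 9, 5
        rows = []
        for j in range(g):
            b = rng.normal(0, 2.0)
            for i in range(n):
                rows.append((f"p{j}", i, 13.0, "Social", "Self", 1, "control",
                             b + rng.normal(0, 0.5)))
        obs = simple_obs(rows)
        spec = pg.GrowthModelSpec(
            "oneway", [()],
            random_blocks=(RandomEffectsBlock("participant", [()], "full"),),
            label_moderation=False)
        fit = fit_lmm(build_design(obs, spec))
        assert satterthwaite_df(fit, {"gamma_000": 1.0}) == pytest.approx(g - 1, rel=1e-3)

    def test_large_df_reproduces_normal_p(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        cr = wald_contrast(fit, {"gamma_300": 1.0})
        from scipy import stats
        p_norm = 2 * stats.norm.sf(abs(cr.t))
        assert cr.p == pytest.approx(p_norm, abs=0.02)


class TestContrasts:
    def test_identity_contrast_matches_coef_table(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        cr = wald_contrast(fit, {"gamma_100": 1.0})
        row = fit.coef_table().loc["gamma_100"]
        assert cr.estimate == pytest.approx(row["b"])
        assert cr.se == pytest.approx(row["se"])
        assert cr.df == pytest.approx(row["df"], rel=1e-6)
        assert cr.ci95[0] < cr.estimate < cr.ci95[1]

    def test_sum_contrast_se_by_hand(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        i, j = 0, 1
        cr = wald_contrast(fit, {fit.gamma.index[i]: 1.0, fit.gamma.index[j]: 1.0})
        S = fit.gamma_cov
        se2 = S[i, i] + S[j, j] + 2 * S[i, j]
        assert cr.se ** 2 == pytest.approx(se2, rel=1e-10)
        assert cr.estimate == pytest.approx(fit.gamma.iloc[i] + fit.gamma.iloc[j])

    def test_zero_weights_rejected(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        with pytest.raises(ValueError, match="degenerate"):
            wald_contrast(fit, {"gamma_100": 0.0})

    def test_unknown_coefficient_rejected(self, crossed_obs, intercepts_spec):
        fit = fit_lmm(build_design(crossed_obs, intercepts_spec))
        with pytest.raises(KeyError, match="gamma_999"):
            wald_contrast(fit, {"gamma_999": 1.0})


class TestModelComparison:
    def test_published_aics_select_larger_model(self):
        cmp = compare_models((462224.6, 35), (461839.9, 151))
        assert cmp.delta_aic == pytest.approx(-384.7, abs=1e-9)
        assert cmp.selected == "b"

    def test_equal_aic_prefers_parsimony(self):
        cmp = compare_models((1000.0, 35), (1000.0, 151))
        assert cmp.selected == "a"

    def test_threshold_edge(self):
        cmp = compare_models((1000.0, 151), (998.1, 35))
        # improvement of 1.9 < 2: fall back to parsimony -> model b (35 params)
        assert cmp.selected == "b"
        cmp2 = compare_models((1000.0, 35), (998.1, 151))
        assert cmp2.selected == "a"

    def test_differing_observation_counts_rejected(self, crossed_obs, intercepts_spec):
        f1 = fit_lmm(build_design(crossed_obs, intercepts_spec))
        obs2 = crossed_obs.iloc[:-4]
        f2 = fit_lmm(build_design(obs2, intercepts_spec))
        with pytest.raises(ValueError, match="observation counts"):
            compare_models(f1, f2)
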