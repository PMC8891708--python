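"""Shared fixtures: small crossed datasets, a dense-likelihood oracle, and
the published Domain-x-Target coefficient estimates used for contrast
arithmetic checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, sparse

import parcelgrowth as pg
from parcelgrowth.design import RandomEffectsBlock, build_design
from parcelgrowth.lmm import _block_lambda, _split_theta


def make_crossed_obs(n_participants=6, n_parcels=4, n_waves=2, seed=0,
                     labels=("control",)):
    """Small fully crossed observation table with random responses."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_participants):
        base_age = rng.uniform(10, 15)
        for w in range(1, n_waves + 1):
            age = base_age + 1.5 * (w - 1)
            for d in ("Academic", "Social"):
                for t in ("Other", "Self"):
                    for k in range(1, n_parcels + 1):
                        lab = labels[(k - 1) % len(labels)]
                        rows.append((f"p{j:02d}", w, age, d, t, k, lab,
                                     rng.normal()))
    obs = pd.DataFrame(rows, columns=["participant_id", "wave", "age", "domain",
                                      "target", "parcel_id", "parcel_label", "bold"])
    return pg.validate_observations(obs)


def dense_deviance(theta, design, y, objective):
    """Independent oracle: build the full marginal covariance V = Z Psi Z' +
    sigma^2 I (relative scale) and evaluate the Gaussian (restricted)
    likelihood directly with dense linear algebra."""
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = design.X.shape
    X = design.X
    Z = sparse.hstack([b["Z"] for b in design.blocks]).toarray()
    ths = _split_theta(theta, design.blocks)
    mats = []
    for b, th in zip(design.blocks, ths):
        L = _block_lambda(b["spec"], th)
        for _ in range(len(b["levels"])):
            mats.append(L @ L.T)
    G = linalg.block_diag(*mats)
    Vr = np.eye(n) + Z @ G @ Z.T
    Vi = np.linalg.inv(Vr)
    XVX = X.T @ Vi @ X
    gam = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ gam
    q = float(r @ Vi @ r)
    sld = np.linalg.slogdet(Vr)[1]
    if objective == "ML":
        s2 = q / n
        return sld + n * np.log(2 * np.pi * s2) + q / s2
    s2 = q / (n - p)
    return sld + np.linalg.slogdet(XVX)[1] + (n - p) * np.log(2 * np.pi * s2) + q / s2


@pytest.fixture
def crossed_obs():
    return make_crossed_obs()


@pytest.fixture
def intercepts_spec():
    """Random intercepts for both grouping factors, minimal fixed part."""
    return pg.GrowthModelSpec(
        "toy", [(), ("age",), ("domain",), ("target",)],
        random_blocks=(RandomEffectsBlock("participant", [()], "full"),
                       RandomEffectsBlock("parcel", [()], "full")),
        label_moderation=False)


#: Published fixed-effect estimates of the Domain x Target model (to the
#: printed 3-decimal precision); used to check contrast arithmetic.
PUBLISHED_GAMMA = {
    "gamma_000": -0.004, "gamma_100": 0.003, "gamma_200": 0.000,
    "gamma_300": 0.013, "gamma_600": 0.004,
    "gamma_001.self": -0.033, "gamma_001.soc": 0.242,
    "gamma_400": 0.000, "gamma_800": 0.002,
    "gamma_101.self": 0.007, "gamma_101.soc": 0.018,
    "gamma_500": -0.003, "gamma_900": -0.002,
    "gamma_201.self": 0.001, "gamma_201.soc": -0.004,
    "gamma_301.self": 0.066, "gamma_301.soc": 0.118,
    "gamma_700": -0.006,
    "gamma_601.self": 0.255, "gamma_601.soc": -0.051,
    "gamma_401.self": -0.006, "gamma_401.soc": -0.005,
    "gamma_801.self": 0.026, "gamma_801.soc": 0.006,
    "gamma_1000": 0.003,
    "gamma_501.self": 0.006, "gamma_501.soc": 0.005,
    "gamma_901.self": -0.011, "gamma_901.soc": 0.004,
    "gamma_1100": -0.000,
    "gamma_701.self": -0.022, "gamma_701.soc": 0.098,
    "gamma_1001.self": -0.006, "gamma_1001.soc": -0.014,
    "gamma_1101.self": 0.009, "gamma_1101.soc": -0.001,
}


@pytest.fixture
def published_fit():
    """LMMFit wrapping the published coefficient table."""
    spec = pg.make_model2_spec()
    gamma = {nm: PUBLISHED_GAMMA[nm] for nm in spec.fixed_names()}
    return pg.fit_from_estimates(gamma)
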