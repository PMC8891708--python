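"""Linear mixed models with crossed random effects (participants x parcels).

Estimation follows the penalized-least-squares formulation of Gaussian
mixed models: each random block has a relative covariance factor
Lambda(theta) (Cholesky-style, scaled by the residual SD), and for a given
theta the fixed effects and residual variance are profiled out of the
(restricted) likelihood analytically.  The optimizer works on the
covariance scale parameters only: the diagonal of the relative Cholesky
factor on the linear scale with a zero lower bound (so boundary fits are
represented exactly), the off-diagonal entries free.  Any Lambda yields a
positive-semidefinite implied covariance.

The model for response vector y is

    y = X gamma + sum_b Z_b u_b + eps,
    u_b ~ N(0, sigma^2 Lambda_b Lambda_b'),  eps ~ N(0, sigma^2 I),

with the blocks b crossing participants and parcels.  Writing
u_b = Lambda_b s_b with spherical s_b, the joint solve for (s, gamma) is a
penalized least-squares problem whose normal-equation Cholesky factor also
yields the two log-determinants the profiled deviance needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats

from .design import DesignMatrices, GrowthModelSpec, RandomEffectsBlock, count_parameters

__all__ = [
    "LMMFit", "ContrastResult", "profiled_deviance", "fit_lmm",
    "satterthwaite_df", "wald_contrast", "compare_models",
    "fit_from_estimates",
]

_SINGULAR_TOL = 1e-3   # relative scale below which a block is at the boundary


# ---------------------------------------------------------------------------
# theta parameterization


def _block_theta_size(blk: RandomEffectsBlock) -> int:
    return blk.n_cov_params


def _split_theta(theta: np.ndarray, blocks: list[dict]) -> list[np.ndarray]:
    out, i = [], 0
    for b in blocks:
        k = _block_theta_size(b["spec"])
        out.append(np.asarray(theta[i:i + k], dtype=float))
        i += k
    if i != len(theta):
        raise ValueError(f"theta has length {len(theta)}, expected {i}")
    return out


def _block_lambda(blk: RandomEffectsBlock, th: np.ndarray) -> np.ndarray:
    """Lower-triangular relative covariance factor for one block.

    The q diagonal entries come first (non-negative, linear scale); for
    full covariance the strictly-lower entries follow, packed row-wise.
    """
    q = blk.q
    L = np.zeros((q, q))
    np.fill_diagonal(L, th[:q])
    if blk.covariance == "full" and q > 1:
        idx = np.tril_indices(q, -1)
        L[idx] = th[q:]
    return L


def theta_init(blocks: list[RandomEffectsBlock] | list[dict]) -> np.ndarray:
    """Starting values: unit relative scales, zero correlations."""
    parts = []
    for b in blocks:
        blk = b["spec"] if isinstance(b, dict) else b
        q = blk.q
        parts.append(np.ones(q))
        if blk.covariance == "full":
            parts.append(np.zeros(q * (q - 1) // 2))
    return np.concatenate(parts) if parts else np.zeros(0)


def _theta_bounds(blocks: list[dict]) -> list[tuple]:
    bounds = []
    for b in blocks:
        blk = b["spec"]
        q = blk.q
        bounds += [(0.0, None)] * q
        if blk.covariance == "full":
            bounds += [(None, None)] * (q * (q - 1) // 2)
    return bounds


# ---------------------------------------------------------------------------
# precomputed cross-products


class _PLSWorkspace:
    """Cross-products of (Z, X, y), assembled once per design.

    Every deviance evaluation then costs one assembly of the penalized
    normal equations and one dense Cholesky of size (m + p), where m is the
    total number of random coefficients.
    """

    def __init__(self, design: DesignMatrices, y: np.ndarray):
        X = np.asarray(design.X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if len(y) != n:
            raise ValueError(f"y has length {len(y)}, design has {n} rows")
        # fixed-design rank check, naming offenders
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        if np.any(diag < tol):
            bad = [design.col_names[j] for j in piv[diag < tol]]
            raise ValueError(f"fixed design is rank deficient; collinear columns: {bad}")

        self.design = design
        self.blocks = design.blocks
        self.X, self.y, self.n, self.p = X, y, n, p
        if self.blocks:
            Z = sparse.hstack([b["Z"] for b in self.blocks]).tocsr()
            self.m = Z.shape[1]
            self.ZtZ = np.asarray((Z.T @ Z).todense())
            self.ZtX = np.asarray(Z.T @ X)
            self.Zty = np.asarray(Z.T @ y).ravel()
        else:
            self.m = 0
            self.ZtZ = np.zeros((0, 0))
            self.ZtX = np.zeros((0, p))
            self.Zty = np.zeros(0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-block column offsets and level counts
        self.offsets, off = [], 0
        for b in self.blocks:
            q = b["spec"].q
            nl = len(b["levels"])
            self.offsets.append((off, q, nl))
            off += q * nl

    def lambda_full(self, theta: np.ndarray) -> sparse.csr_matrix:
        """Block-diagonal Lambda over all random coefficients (level-major)."""
        ths = _split_theta(theta, self.blocks)
        parts = []
        for b, th in zip(self.blocks, ths):
            Lb = _block_lambda(b["spec"], th)
            nl = len(b["levels"])
            parts.append(sparse.kron(sparse.identity(nl, format="csr"),
                                     sparse.csr_matrix(Lb)))
        return sparse.block_diag(parts, format="csr") if parts else sparse.csr_matrix((0, 0))

    def solve(self, theta: np.ndarray):
        """Cholesky solve of the penalized normal equations at theta.

        Returns (logdet_Vr, logdet_XVX, pwrss, gamma, u_spherical, chol, Lam).
        """
        m, p = self.m, self.p
        if m:
            Lam = self.lambda_full(theta)
            B = Lam.T @ self.ZtZ            # m x m dense
            LtZtZL = Lam.T @ B.T            # Lambda' ZtZ Lambda (ZtZ symmetric)
            A = np.empty((m + p, m + p))
            A[:m, :m] = LtZtZL
            A[:m, :m][np.diag_indices(m)] += 1.0
            A[:m, m:] = Lam.T @ self.ZtX
            A[m:, :m] = A[:m, m:].T
            A[m:, m:] = self.XtX
            rhs = np.concatenate([Lam.T @ self.Zty, self.Xty])
        else:
            Lam = None
            A = self.XtX.copy()
            rhs = self.Xty.copy()
        C, low = linalg.cho_factor(A, lower=True, check_finite=False)
        sol = linalg.cho_solve((C, low), rhs, check_finite=False)
        pwrss = max(self.yty - float(rhs @ sol), 1e-12)
        d = np.diag(C)
        logdet_Vr = 2.0 * float(np.sum(np.log(d[:m])))
        logdet_XVX = 2.0 * float(np.sum(np.log(d[m:])))
        return logdet_Vr, logdet_XVX, pwrss, sol[m:], sol[:m], (C, low), Lam

    def deviance(self, theta: np.ndarray, objective: str) -> float:
        """Profiled deviance: -2 log (restricted) likelihood, gamma and
        sigma^2 concentrated out."""
        logdet_Vr, logdet_XVX, pwrss, *_ = self.solve(theta)
        n, p = self.n, self.p
        if objective == "ML":
            return logdet_Vr + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
        if objective == "REML":
            return (logdet_Vr + logdet_XVX
                    + (n - p) * (1.0 + np.log(2.0 * np.pi * pwrss / (n - p))))
        raise ValueError(f"objective must be ML or REML, got {objective!r}")

    def deviance_full(self, theta: np.ndarray, sigma2: float, objective: str) -> float:
        """-2 log (restricted) likelihood as a joint function of (theta, sigma^2);
        used for curvature in the Satterthwaite approximation."""
        logdet_Vr, logdet_XVX, pwrss, *_ = self.solve(theta)
        n, p = self.n, self.p
        if objective == "ML":
            return (logdet_Vr + pwrss / sigma2
                    + n * np.log(2.0 * np.pi * sigma2))
        return (logdet_Vr + logdet_XVX + pwrss / sigma2
                + (n - p) * np.log(2.0 * np.pi * sigma2))

    def gamma_cov_rel(self, theta: np.ndarray,
                      solved: tuple | None = None) -> np.ndarray:
        """(X' Vr^{-1} X)^{-1}: covariance of gamma-hat relative to sigma^2.

        The trailing p x p block L22 of the penalized-system Cholesky factor
        satisfies L22 L22' = X' Vr^{-1} X.
        """
        C, low = (solved or self.solve(theta))[5]
        m = self.m
        inv = linalg.solve_triangular(C[m:, m:], np.eye(self.p),
                                      lower=True, check_finite=False)
        return inv.T @ inv


def profiled_deviance(theta, design: DesignMatrices, y, objective: str = "REML",
                      workspace: _PLSWorkspace | None = None) -> float:
    """Profiled deviance of a crossed-random-effects Gaussian mixed model.

    Parameters
    ----------
    theta : array
        Stacked relative-Cholesky parameters over the design's random
        blocks (log-diagonal first, then free off-diagonals, per block).
    design : DesignMatrices
    y : array
        Response vector.
    objective : {'REML', 'ML'}
    """
    ws = workspace or _PLSWorkspace(design, np.asarray(y, dtype=float))
    return ws.deviance(np.asarray(theta, dtype=float), objective)


# ---------------------------------------------------------------------------
# fit result containers


@dataclass
class BlockEstimate:
    spec: RandomEffectsBlock
    psi: np.ndarray              # q x q covariance of group deviations
    levels: np.ndarray
    blups: pd.DataFrame | None = None


@dataclass
class LMMFit:
    """Fitted cross-classified mixed model."""

    gamma: pd.Series             # named fixed-effect estimates
    gamma_cov: np.ndarray        # p x p covariance of the estimates
    sigma2: float
    blocks: list[BlockEstimate]
    theta: np.ndarray
    objective: str
    deviance: float
    n_params: int
    n_obs: int
    converged: bool
    singular: bool
    spec: GrowthModelSpec | None = None
    optimizer_message: str = ""
    n_deviance_evals: int = 0
    _workspace: _PLSWorkspace | None = field(default=None, repr=False)
    _hessian_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.n_params

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.gamma_cov)), index=self.gamma.index)

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table with Wald t statistics, Satterthwaite df,
        two-sided p values and 95% CIs."""
        rows = []
        dfs = satterthwaite_df_batch(self, np.eye(len(self.gamma)))
        se = self.se()
        for i, name in enumerate(self.gamma.index):
            est, s = self.gamma.iloc[i], se.iloc[i]
            t = est / s if s > 0 else np.nan
            df = dfs[i]
            p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            crit = stats.t.ppf(0.975, df)
            rows.append((name, est, s, t, df, p, est - crit * s, est + crit * s))
        return pd.DataFrame(rows, columns=["term", "b", "se", "t", "df", "p",
                                           "ci_lo", "ci_hi"]).set_index("term")

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma.to_dict(),
            "se": self.se().to_dict(),
            "sigma2": self.sigma2,
            "psi": {f"{b.spec.grouping}": b.psi.tolist() for b in self.blocks},
            "objective": self.objective,
            "deviance": self.deviance,
            "n_params": self.n_params,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "singular": bool(self.singular),
        }


@dataclass
class ContrastResult:
    """Wald inference for a linear combination of fixed effects."""

    weights: pd.Series
    estimate: float
    se: float
    t: float
    df: float
    p: float
    ci95: tuple[float, float]

    def __repr__(self):
        return (f"ContrastResult(estimate={self.estimate:.4g}, se={self.se:.4g}, "
                f"t={self.t:.3f}, df={self.df:.1f}, p={self.p:.4g})")


# ---------------------------------------------------------------------------
# fitting


def fit_lmm(design: DesignMatrices, y=None, spec: GrowthModelSpec | None = None,
            objective: str = "REML", theta0: np.ndarray | None = None,
            maxiter: int = 500) -> LMMFit:
    """Fit a crossed-random-effects Gaussian mixed model.

    Minimizes the profiled deviance over the relative-Cholesky scale
    parameters (L-BFGS-B, finite-difference gradients), then recovers the
    fixed effects, residual variance, per-block covariance matrices and
    conditional modes (BLUPs).  Boundary fits (any relative scale
    effectively zero) are flagged ``singular`` rather than raised.
    """
    if y is None:
        y = design.y
    if y is None:
        raise ValueError("no response vector: pass y or a design built with bold values")
    y = np.asarray(y, dtype=float)
    ws = _PLSWorkspace(design, y)

    for b in design.blocks:
        if len(b["levels"]) < 2:
            raise ValueError(
                f"grouping factor {b['spec'].grouping!r} has fewer than 2 levels")

    n_theta = sum(_block_theta_size(b["spec"]) for b in design.blocks)
    evals = [0]

    if n_theta:
        def obj(th):
            evals[0] += 1
            return ws.deviance(th, objective)

        th0 = theta_init(design.blocks) if theta0 is None else np.asarray(theta0, float)
        # Powell handles the flat region near the variance boundary far more
        # reliably here than gradient-based methods with FD gradients
        res = optimize.minimize(
            obj, th0, method="Powell", bounds=_theta_bounds(design.blocks),
            options={"maxiter": maxiter, "xtol": 1e-8, "ftol": 1e-10})
        theta = res.x
        converged = bool(res.success)
        message = str(res.message)
        dev = float(res.fun)
    else:
        theta = np.zeros(0)
        converged, message = True, "no random effects: generalized least squares"
        dev = ws.deviance(theta, objective)

    solved = ws.solve(theta)
    logdet_Vr, logdet_XVX, pwrss, gamma, u_sph, chol, Lam = solved
    dof = ws.n if objective == "ML" else ws.n - ws.p
    sigma2 = pwrss / dof
    gamma_cov = sigma2 * ws.gamma_cov_rel(theta, solved=solved)

    # per-block covariance estimates and conditional modes (u = Lambda s is
    # the BLUP on the response scale)
    blocks_out, singular = [], False
    ths = _split_theta(theta, design.blocks)
    u_full = np.asarray(Lam @ u_sph).ravel() if ws.m else np.zeros(0)
    for b, th, (off, q, nl) in zip(design.blocks, ths, ws.offsets):
        Lb = _block_lambda(b["spec"], th)
        psi = sigma2 * (Lb @ Lb.T)
        if np.any(th[:q] < _SINGULAR_TOL):
            singular = True
        blup_mat = u_full[off:off + q * nl].reshape(nl, q)
        blups = pd.DataFrame(blup_mat, index=pd.Index(b["levels"], name=b["spec"].grouping),
                             columns=[" * ".join(t) if t else "intercept" for t in b["spec"].terms])
        blocks_out.append(BlockEstimate(spec=b["spec"], psi=psi,
                                        levels=b["levels"], blups=blups))

    n_params = ws.p + n_theta + 1
    fit = LMMFit(
        gamma=pd.Series(gamma, index=design.col_names),
        gamma_cov=gamma_cov, sigma2=sigma2, blocks=blocks_out,
        theta=theta, objective=objective, deviance=dev,
        n_params=n_params, n_obs=ws.n, converged=converged,
        singular=singular, spec=spec, optimizer_message=message,
        n_deviance_evals=evals[0], _workspace=ws)
    return fit


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom


def _phi_pack(fit: LMMFit) -> np.ndarray:
    return np.concatenate([fit.theta, [np.log(fit.sigma2)]])


def _contrast_var_fn(fit: LMMFit):
    """c' Cov(gamma-hat) c as a function of phi = (theta, log sigma^2),
    vectorized over a stack of contrasts."""
    ws = fit._workspace

    def f(phi, Cmat):
        theta, s2 = phi[:-1], np.exp(phi[-1])
        rel = ws.gamma_cov_rel(theta)
        return s2 * np.einsum("ij,jk,ik->i", Cmat, rel, Cmat)

    return f


def _deviance_hessian_inv(fit: LMMFit) -> np.ndarray:
    """Inverse curvature of the (restricted) deviance in phi at the optimum.

    2 * H^{-1} approximates the covariance of the variance-parameter
    estimates.  Cached on the fit; indefinite curvature returns None.
    """
    if fit._hessian_inv is not None:
        return fit._hessian_inv
    ws = fit._workspace
    phi0 = _phi_pack(fit)
    k = len(phi0)

    def dev(phi):
        return ws.deviance_full(phi[:-1], np.exp(phi[-1]), fit.objective)

    h = 1e-4 * np.maximum(np.abs(phi0), 1.0)
    H = np.empty((k, k))
    f0 = dev(phi0)
    # central second differences
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        fp[i] = dev(phi0 + e)
        fm[i] = dev(phi0 - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = dev(phi0 + ei + ej)
            fmm = dev(phi0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j])
    try:
        # covariance of phi-hat is 2 H^{-1}; require positive definite H
        Hc = linalg.cho_factor(H)
        Hinv = linalg.cho_solve(Hc, np.eye(k))
    except linalg.LinAlgError:
        fit._hessian_inv = None
        return None
    fit._hessian_inv = Hinv
    return Hinv


def satterthwaite_df_batch(fit: LMMFit, Cmat: np.ndarray) -> np.ndarray:
    """Satterthwaite df for each row of a contrast matrix.

    df = 2 [Var(c'g)]^2 / Var[Var(c'g)], with the denominator from the delta
    method: the gradient of c'Cov(gamma)c with respect to the variance
    parameters, against the inverse curvature of the deviance.  Falls back
    to +inf (normal approximation) when the curvature is not positive
    definite.
    """
    Cmat = np.atleast_2d(np.asarray(Cmat, dtype=float))
    if fit._workspace is None:
        # fit assembled from externally supplied estimates: no deviance
        # surface to differentiate, use the normal approximation
        return np.full(Cmat.shape[0], np.inf)
    Hinv = _deviance_hessian_inv(fit)
    if Hinv is None:
        warnings.warn("deviance curvature not positive definite; "
                      "using normal approximation (df = inf)")
        return np.full(Cmat.shape[0], np.inf)
    f = _contrast_var_fn(fit)
    phi0 = _phi_pack(fit)
    k = len(phi0)
    h = 1e-4 * np.maximum(np.abs(phi0), 1.0)
    grads = np.empty((Cmat.shape[0], k))
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        grads[:, i] = (f(phi0 + e, Cmat) - f(phi0 - e, Cmat)) / (2 * h[i])
    var_c = f(phi0, Cmat)
    # Var(phi) ~= 2 Hinv
    var_of_var = 2.0 * np.einsum("ri,ij,rj->r", grads, Hinv, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * var_c ** 2 / var_of_var
    df = np.where((var_of_var <= 0) | ~np.isfinite(df), np.inf, df)
    return np.maximum(df, np.finfo(float).tiny)


def satterthwaite_df(fit: LMMFit, weights) -> float:
    """Satterthwaite degrees of freedom for a single contrast."""
    c = _weights_to_vector(fit, weights)
    return float(satterthwaite_df_batch(fit, c[None, :])[0])


def _weights_to_vector(fit: LMMFit, weights) -> np.ndarray:
    if isinstance(weights, dict) or isinstance(weights, pd.Series):
        w = pd.Series(weights, dtype=float)
        unknown = [k for k in w.index if k not in fit.gamma.index]
        if unknown:
            raise KeyError(f"contrast names absent from the fit: {unknown}")
        c = np.zeros(len(fit.gamma))
        for k, v in w.items():
            c[fit.gamma.index.get_loc(k)] = v
        return c
    c = np.asarray(weights, dtype=float)
    if c.shape != (len(fit.gamma),):
        raise ValueError(f"weight vector has shape {c.shape}, expected ({len(fit.gamma)},)")
    return c


def wald_contrast(fit: LMMFit, weights) -> ContrastResult:
    """t test of a named linear combination of fixed effects.

    SE from the fixed-effect covariance, df by the Satterthwaite
    approximation, two-sided p, 95% CI.
    """
    c = _weights_to_vector(fit, weights)
    if not np.any(c):
        raise ValueError("degenerate contrast: all weights are zero")
    est = float(c @ fit.gamma.to_numpy())
    se = float(np.sqrt(c @ fit.gamma_cov @ c))
    df = satterthwaite_df(fit, c)
    t = est / se if se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    return ContrastResult(
        weights=pd.Series(c, index=fit.gamma.index), estimate=est, se=se,
        t=t, df=df, p=p, ci95=(est - crit * se, est + crit * se))


def fit_from_estimates(gamma, gamma_cov=None, sigma2: float = 1.0,
                       objective: str = "REML") -> LMMFit:
    """Wrap externally supplied fixed-effect estimates as an LMMFit.

    Useful for applying contrast arithmetic (simple slopes, trajectory
    prediction) to a published coefficient table.  Contrast degrees of
    freedom fall back to the normal approximation since no deviance surface
    is available.
    """
    gamma = pd.Series(gamma, dtype=float)
    p = len(gamma)
    cov = np.zeros((p, p)) if gamma_cov is None else np.asarray(gamma_cov, float)
    if cov.shape != (p, p):
        raise ValueError(f"gamma_cov has shape {cov.shape}, expected ({p}, {p})")
    return LMMFit(gamma=gamma, gamma_cov=cov, sigma2=sigma2, blocks=[],
                  theta=np.zeros(0), objective=objective, deviance=np.nan,
                  n_params=p + 1, n_obs=0, converged=True, singular=False)


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    aic_a: float
    aic_b: float
    delta_aic: float             # b - a
    n_params_a: int
    n_params_b: int
    selected: str                # 'a' or 'b'

    def to_dict(self):
        return {"aic_a": self.aic_a, "aic_b": self.aic_b,
                "delta_aic": self.delta_aic, "selected": self.selected,
                "n_params": {"a": self.n_params_a, "b": self.n_params_b}}


def compare_models(fit_a, fit_b, threshold: float = 2.0) -> ModelComparison:
    """AIC comparison: the challenger wins only if it lowers AIC by at least
    the threshold; otherwise ties go to the more parsimonious model.

    Accepts LMMFit objects or (aic, n_params) pairs.
    """
    def unpack(f):
        if isinstance(f, LMMFit):
            return f.aic, f.n_params, f.n_obs
        aic, k = f
        return float(aic), int(k), None

    aic_a, k_a, n_a = unpack(fit_a)
    aic_b, k_b, n_b = unpack(fit_b)
    if n_a is not None and n_b is not None and n_a != n_b:
        raise ValueError(f"models fitted to different observation counts: {n_a} vs {n_b}")
    if isinstance(fit_a, LMMFit) and isinstance(fit_b, LMMFit) \
            and fit_a.objective != fit_b.objective:
        raise ValueError("models fitted under different objectives are not comparable")
    delta = aic_b - aic_a
    if delta <= -threshold:
        selected = "b"
    elif delta >= threshold:
        selected = "a"
    else:
        selected = "b" if k_b < k_a else "a"
    return ModelComparison(aic_a=aic_a, aic_b=aic_b, delta_aic=delta,
                           n_params_a=k_a, n_params_b=k_b, selected=selected)
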