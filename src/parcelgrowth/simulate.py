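"""Synthetic longitudinal cohorts and parcel-level datasets.

Emulates an accelerated three-wave adolescent fMRI cohort: waves of 57, 44
and 34 scanned sessions drawn from 74 unique participants (35 with one
wave, 17 with two, 22 with all three), wave ages centred near 10.1, 13.1
and 16.3 years.  Responses are generated from the cross-classified growth
model read generatively: fixed-effect surface plus participant deviations,
parcel deviations and i.i.d. Gaussian residual noise.  Small NIfTI fixtures
exercise the extraction stage end-to-end.

Everything is reproducible bit-for-bit from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from . import design as dz
from .design import GrowthModelSpec, build_design, validate_observations

__all__ = [
    "CohortDesign", "SimulationConfig", "simulate_cohort",
    "simulate_observations", "generate_nifti_fixture", "recovery_experiment",
    "PAPER_COHORT", "reduced_recovery_config",
]


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of an accelerated longitudinal cohort."""

    wave_sizes: tuple = (57, 44, 34)
    age_means: tuple = (10.08, 13.06, 16.33)
    age_sds: tuple = (0.32, 0.33, 0.46)
    retention: tuple = (35, 17, 22)        # participants with 1, 2, 3 waves
    age_range: tuple = (9.0, 17.5)
    wave_gap_mean: float = 3.0             # years between adjacent waves
    wave_gap_sd: float = 0.3
    parcel_counts: dict = field(default_factory=lambda: {"self": 19, "social": 44,
                                                         "control": 289})

    @property
    def n_participants(self) -> int:
        return sum(self.retention)

    @property
    def n_sessions(self) -> int:
        return sum(k * r for k, r in enumerate(self.retention, start=1))

    def validate(self):
        if self.n_sessions != sum(self.wave_sizes):
            raise ValueError(
                f"retention implies {self.n_sessions} sessions but wave sizes "
                f"sum to {sum(self.wave_sizes)}")
        _allocate_wave_sets(self)  # raises if infeasible
        return self


#: The study cohort: 135 sessions from 74 adolescents over three waves.
PAPER_COHORT = CohortDesign()


def _allocate_wave_sets(design: CohortDesign) -> list[tuple[int, ...]]:
    """Deterministically assign each participant a set of attended waves.

    Greedy: 3-wave participants attend all waves; each 2-wave participant
    takes the two waves with most unfilled slots; singles fill what is
    left.  Raises if the per-wave totals cannot be met.
    """
    remaining = list(design.wave_sizes)
    n1, n2, n3 = design.retention
    sets: list[tuple[int, ...]] = []
    for _ in range(n3):
        sets.append((1, 2, 3))
        for w in range(3):
            remaining[w] -= 1
    for _ in range(n2):
        order = sorted(range(3), key=lambda w: -remaining[w])[:2]
        if min(remaining[w] for w in order) < 1:
            raise ValueError("infeasible retention/wave-size combination")
        for w in order:
            remaining[w] -= 1
        sets.append(tuple(sorted(w + 1 for w in order)))
    for _ in range(n1):
        w = int(np.argmax(remaining))
        if remaining[w] < 1:
            raise ValueError("infeasible retention/wave-size combination")
        remaining[w] -= 1
        sets.append((w + 1,))
    if any(r != 0 for r in remaining):
        raise ValueError("infeasible retention/wave-size combination")
    return sets


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal; deterministic given the generator."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = (out < lo) | (out > hi)
    return out


def simulate_cohort(design: CohortDesign = PAPER_COHORT, seed: int = 0) -> pd.DataFrame:
    """Draw a demographics table (participant_id, wave, age) for the design.

    Each participant's first attended wave gets an age from that wave's
    truncated normal; later attended waves add ~N(gap_mean, gap_sd) years
    per wave step, so within-participant ages are longitudinally linked.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    sets = _allocate_wave_sets(design)
    lo, hi = design.age_range
    rows = []
    for i, waves in enumerate(sets):
        pid = f"s{i + 1:03d}"
        first = waves[0]
        age = float(_truncnorm(rng, design.age_means[first - 1],
                               design.age_sds[first - 1], lo, hi))
        prev_wave, prev_age = first, age
        rows.append((pid, first, age))
        for w in waves[1:]:
            steps = w - prev_wave
            gap = float(rng.normal(design.wave_gap_mean * steps,
                                   design.wave_gap_sd * np.sqrt(steps)))
            a = float(np.clip(prev_age + gap, lo, hi))
            rows.append((pid, w, a))
            prev_wave, prev_age = w, a
    return pd.DataFrame(rows, columns=["participant_id", "wave", "age"])


def _parcel_table(design: CohortDesign) -> pd.DataFrame:
    rows, pid = [], 1
    for label in ("self", "social", "control"):
        for _ in range(design.parcel_counts.get(label, 0)):
            rows.append((pid, label))
            pid += 1
    return pd.DataFrame(rows, columns=["parcel_id", "parcel_label"])


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for a synthetic parcel-level dataset.

    ``true_gamma`` maps fixed-effect names (as produced by the model spec)
    to values; unnamed coefficients are zero.  ``participant_cov`` and
    ``parcel_cov`` are the covariance matrices of the group deviations for
    the spec's random blocks, in block-term order.
    """

    true_gamma: dict
    participant_cov: np.ndarray | None
    parcel_cov: np.ndarray | None
    residual_var: float = 1.0
    design: CohortDesign = PAPER_COHORT
    seed: int = 0

    def validate(self, spec: GrowthModelSpec):
        names = set(spec.fixed_names())
        unknown = [k for k in self.true_gamma if k not in names]
        if unknown:
            raise ValueError(f"true_gamma names not in spec: {unknown}")
        if self.residual_var <= 0:
            raise ValueError("residual_var must be positive")
        covs = {"participant": self.participant_cov, "parcel": self.parcel_cov}
        for blk in spec.random_blocks:
            cov = covs[blk.grouping]
            if cov is None:
                raise ValueError(f"spec has a {blk.grouping} block but no covariance given")
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (blk.q, blk.q):
                raise ValueError(
                    f"{blk.grouping} covariance is {cov.shape}, block has q={blk.q}")
            ev = np.linalg.eigvalsh((cov + cov.T) / 2)
            if ev.min() < -1e-10:
                raise ValueError(f"{blk.grouping} covariance is not PSD")
        return self


def simulate_observations(config: SimulationConfig, spec: GrowthModelSpec,
                          demographics: pd.DataFrame | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Generate an observation table from the growth model read generatively.

    Participant and parcel deviations are multivariate normal with the
    configured covariances; the residual is i.i.d. Gaussian.  Returns a
    validated long table.
    """
    config.validate(spec)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if demographics is None:
        demographics = simulate_cohort(config.design, seed=rng.integers(2 ** 31))
    parcels = _parcel_table(config.design)

    # full factorial: session x condition x parcel
    conditions = pd.DataFrame(
        [(d, t) for d in ("Academic", "Social") for t in ("Other", "Self")],
        columns=["domain", "target"])
    obs = (demographics.merge(conditions, how="cross")
           .merge(parcels, how="cross"))
    obs["bold"] = 0.0
    obs = validate_observations(obs)

    dm = build_design(obs, spec)
    gamma = np.zeros(dm.p)
    for k, v in config.true_gamma.items():
        gamma[dm.col_names.index(k)] = v
    y = dm.X @ gamma

    covs = {"participant": config.participant_cov, "parcel": config.parcel_cov}
    for b in dm.blocks:
        blk = b["spec"]
        cov = np.asarray(covs[blk.grouping], dtype=float)
        nl = len(b["levels"])
        u = rng.multivariate_normal(np.zeros(blk.q), cov, size=nl,
                                    method="cholesky" if _is_pd(cov) else "svd")
        y = y + b["Z"] @ u.ravel()          # level-major matches Z columns
    y = y + rng.normal(0.0, np.sqrt(config.residual_var), size=len(obs))
    obs["bold"] = y
    return obs


def _is_pd(cov):
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# NIfTI fixtures


def generate_nifti_fixture(shape, parcel_geometry: dict, parcel_means: dict,
                           noise_sd: float = 0.0, seed: int = 0,
                           voxel_size: float = 3.0):
    """Build a (contrast image, atlas) NIfTI pair with known parcel means.

    ``parcel_geometry`` maps parcel_id to a boolean mask of ``shape``;
    regions must be disjoint.  In-parcel image values are the stated mean
    plus N(0, noise_sd) noise; background is zero.
    """
    shape = tuple(shape)
    labels = np.zeros(shape, dtype=np.int16)
    occupancy = np.zeros(shape, dtype=bool)
    for pid, mask in parcel_geometry.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask for parcel {pid} has shape {mask.shape}, expected {shape}")
        if np.any(occupancy & mask):
            raise ValueError(f"parcel {pid} overlaps a previous region")
        occupancy |= mask
        labels[mask] = pid

    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.float64)
    for pid, mask in parcel_geometry.items():
        mu = float(parcel_means[pid])
        vals = np.full(int(np.asarray(mask).sum()), mu)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
        data[np.asarray(mask, dtype=bool)] = vals

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return nib.Nifti1Image(data, affine), nib.Nifti1Image(labels, affine)


# ---------------------------------------------------------------------------
# parameter recovery


def reduced_recovery_config(true_gamma: dict | None = None,
                            seed: int = 0) -> tuple[SimulationConfig, GrowthModelSpec]:
    """Desk-scale recovery setup: 40 participants, 30 parcels, 4 conditions.

    The fixed structure is the full Domain-x-Target model (36 coefficients);
    random intercepts and age slopes for both participants and parcels with
    modest correlation, variances in the range typical of standardized
    parcel estimates.  Keeps a simulate-and-fit cycle to roughly a second.
    """
    from .pipeline import make_model2_spec  # local import to avoid a cycle

    cohort = CohortDesign(
        wave_sizes=(31, 24, 18), retention=(19, 9, 12),
        parcel_counts={"self": 6, "social": 9, "control": 15})
    spec = make_model2_spec().with_random_blocks([
        dz.RandomEffectsBlock("participant", [(), ("age",)], "full"),
        dz.RandomEffectsBlock("parcel", [(), ("age",)], "full"),
    ])
    if true_gamma is None:
        true_gamma = {
            "gamma_000": -0.004, "gamma_100": 0.003, "gamma_200": 0.000,
            "gamma_300": 0.013, "gamma_600": 0.004,
            "gamma_001.soc": 0.242, "gamma_101.soc": 0.018,
            "gamma_201.soc": -0.004, "gamma_301.soc": 0.118,
            "gamma_601.self": 0.255, "gamma_801.self": 0.026,
            "gamma_901.self": -0.011,
        }
    config = SimulationConfig(
        true_gamma=true_gamma,
        participant_cov=np.array([[0.040, 0.002], [0.002, 0.004]]),
        parcel_cov=np.array([[0.090, 0.003], [0.003, 0.006]]),
        residual_var=0.8, design=cohort, seed=seed)
    return config, spec


def recovery_experiment(config: SimulationConfig, spec: GrowthModelSpec,
                        replicates: int, seed: int = 0,
                        objective: str = "REML",
                        alpha: float = 0.05) -> dict:
    """Simulate -> fit -> summarize, over many seeded replicates.

    For every fixed effect records the mean estimate, bias, RMSE, empirical
    95% CI coverage (Wald intervals with Satterthwaite df) and the
    rejection rate of the two-sided t test at ``alpha``.  Monte-Carlo
    standard errors accompany bias and coverage.  Failed replicates are
    recorded, not fatal.
    """
    from .lmm import fit_lmm, satterthwaite_df_batch
    from scipy import stats as sps

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config.validate(spec)
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(replicates)]

    names = spec.fixed_names()
    p = len(names)
    truth = np.array([config.true_gamma.get(nm, 0.0) for nm in names])
    est = np.full((replicates, p), np.nan)
    cover = np.full((replicates, p), np.nan)
    reject = np.full((replicates, p), np.nan)
    failures = []

    for r, s in enumerate(child_seeds):
        try:
            obs = simulate_observations(config, spec, seed=s)
            dm = build_design(obs, spec)
            fit = fit_lmm(dm, objective=objective)
            g = fit.gamma.to_numpy()
            se = fit.se().to_numpy()
            dfs = satterthwaite_df_batch(fit, np.eye(p))
            crit = sps.t.ppf(1 - alpha / 2, dfs)
            est[r] = g
            cover[r] = np.abs(g - truth) <= crit * se
            reject[r] = np.abs(g / se) > crit
        except Exception as exc:   # noqa: BLE001 - per-replicate robustness
            failures.append({"replicate": r, "seed": s, "error": repr(exc)})

    ok = ~np.isnan(est[:, 0])
    R = int(ok.sum())
    bias = est[ok].mean(axis=0) - truth
    bias_mcse = est[ok].std(axis=0, ddof=1) / np.sqrt(R)
    rmse = np.sqrt(((est[ok] - truth) ** 2).mean(axis=0))
    cov_rate = cover[ok].mean(axis=0)
    cov_mcse = np.sqrt(cov_rate * (1 - cov_rate) / R)
    rej_rate = reject[ok].mean(axis=0)
    # pooled coverage with replicate-clustered MCSE (coefficients within a
    # replicate share data and are correlated)
    per_rep_cov = cover[ok].mean(axis=1)
    pooled_cov = float(per_rep_cov.mean())
    pooled_cov_mcse = float(per_rep_cov.std(ddof=1) / np.sqrt(R))

    table = pd.DataFrame({
        "term": names, "truth": truth, "mean_est": est[ok].mean(axis=0),
        "bias": bias, "bias_mcse": bias_mcse, "rmse": rmse,
        "coverage": cov_rate, "coverage_mcse": cov_mcse,
        "reject_rate": rej_rate,
    }).set_index("term")
    return {
        "n_replicates": replicates, "n_ok": R, "failures": failures,
        "per_coefficient": table,
        "pooled_coverage": pooled_cov,
        "pooled_coverage_mcse": pooled_cov_mcse,
        "seed": seed, "objective": objective, "alpha": alpha,
    }
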