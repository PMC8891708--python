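"""Study design: factor coding, age centering, growth-model terms and design matrices.

The analysis models parcel-level BOLD estimates from a 2x2 task design
(Domain: Academic/Social crossed with Target: Other/Self) measured over up
to three longitudinal waves, with observations cross-classified by
participant and brain parcel.  Both factors are effect-coded at -0.5/+0.5
so the intercept is the cell average, age is centred at 13 years so the
intercept and linear terms refer to mid-adolescence, and every within-cell
growth term is moderated by the parcel category (control as reference,
with self and social indicator columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

AGE_CENTER = 13.0

DOMAIN_CODE = {"Academic": -0.5, "Social": 0.5}
TARGET_CODE = {"Other": -0.5, "Self": 0.5}
PARCEL_LABELS = ("control", "self", "social")

#: Canonical within-cell growth terms, indexed by their coefficient-equation
#: position.  A term is a tuple of covariate tokens whose product forms the
#: regressor; () is the intercept.
GROWTH_TERMS: tuple[tuple[str, ...], ...] = (
    (),                          # 0: intercept
    ("age",),                    # 1
    ("age2",),                   # 2
    ("domain",),                 # 3
    ("age", "domain"),           # 4
    ("age2", "domain"),          # 5
    ("target",),                 # 6
    ("domain", "target"),        # 7
    ("age", "target"),           # 8
    ("age2", "target"),          # 9
    ("age", "domain", "target"),  # 10
    ("age2", "domain", "target"),  # 11
)

_TOKEN_LABEL = {"age": "Age", "age2": "Age^2", "domain": "Domain", "target": "Target"}

OBSERVATION_COLUMNS = (
    "participant_id", "wave", "age", "domain", "target",
    "parcel_id", "parcel_label", "bold",
)


def term_index(term: tuple[str, ...]) -> int:
    """Position of a growth term in the canonical coefficient-equation order."""
    return GROWTH_TERMS.index(tuple(term))


def gamma_name(term: tuple[str, ...], label: str) -> str:
    """Fixed-effect coefficient name for a growth term at a parcel-label level.

    Follows the subscript scheme of the coefficient equations: the control
    (reference) column of term *t* is ``gamma_{t}00``; the label-moderation
    columns are ``gamma_{t}01.self`` and ``gamma_{t}01.soc``.
    """
    t = term_index(term)
    if label == "control":
        return f"gamma_{t}00"
    if label == "self":
        return f"gamma_{t}01.self"
    if label == "social":
        return f"gamma_{t}01.soc"
    raise ValueError(f"unknown parcel label {label!r}; expected one of {PARCEL_LABELS}")


def term_label(term: tuple[str, ...], label: str) -> str:
    """Human-readable name, e.g. 'Age x Target x Label (self)'."""
    parts = [_TOKEN_LABEL[tok] for tok in term]
    if label != "control":
        parts.append(f"Label ({label})")
    if not parts:
        return "Intercept (control label, age 13)"
    return " x ".join(parts)


def center_age(age_years):
    """Centre age at 13 years; the quadratic regressor is the square of this."""
    age = np.asarray(age_years, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite to be centred")
    out = age - AGE_CENTER
    return float(out) if np.isscalar(age_years) else out


def code_condition(domain: str, target: str) -> tuple[float, float]:
    """Numeric codes for a task cell: Social/Self -> +0.5, Academic/Other -> -0.5."""
    if domain not in DOMAIN_CODE:
        raise ValueError(f"unknown domain {domain!r}; valid levels: {sorted(DOMAIN_CODE)}")
    if target not in TARGET_CODE:
        raise ValueError(f"unknown target {target!r}; valid levels: {sorted(TARGET_CODE)}")
    return DOMAIN_CODE[domain], TARGET_CODE[target]


@dataclass(frozen=True)
class RandomEffectsBlock:
    """Random-effects specification for one crossed grouping factor.

    Parameters
    ----------
    grouping : {'participant', 'parcel'}
        Which cross-classification the deviations attach to.
    terms : sequence of growth terms
        The coefficient equations that receive a group deviation.
    covariance : {'full', 'diagonal'}
        Whether deviations within the block covary freely or independently.
    """

    grouping: str
    terms: tuple[tuple[str, ...], ...]
    covariance: str = "full"

    def __post_init__(self):
        if self.grouping not in ("participant", "parcel"):
            raise ValueError(f"grouping must be participant or parcel, got {self.grouping!r}")
        if self.covariance not in ("full", "diagonal"):
            raise ValueError(f"covariance must be full or diagonal, got {self.covariance!r}")
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        if len(self.terms) < 1:
            raise ValueError("a random block needs at least one term")
        for t in self.terms:
            term_index(t)  # validates membership

    @property
    def q(self) -> int:
        return len(self.terms)

    @property
    def n_cov_params(self) -> int:
        q = self.q
        return q * (q + 1) // 2 if self.covariance == "full" else q


@dataclass(frozen=True)
class GrowthModelSpec:
    """A polynomial growth model: fixed growth terms plus crossed random blocks.

    With ``label_moderation`` every base term is crossed with the two parcel
    category indicators, giving three fixed columns per term.
    """

    name: str
    base_terms: tuple[tuple[str, ...], ...]
    random_blocks: tuple[RandomEffectsBlock, ...] = ()
    label_moderation: bool = True

    def __post_init__(self):
        object.__setattr__(self, "base_terms", tuple(tuple(t) for t in self.base_terms))
        object.__setattr__(self, "random_blocks", tuple(self.random_blocks))
        for t in self.base_terms:
            term_index(t)

    @property
    def n_fixed(self) -> int:
        return (3 if self.label_moderation else 1) * len(self.base_terms)

    def fixed_names(self) -> list[str]:
        names = []
        for t in self.base_terms:
            names.append(gamma_name(t, "control"))
            if self.label_moderation:
                names.append(gamma_name(t, "self"))
                names.append(gamma_name(t, "social"))
        return names

    def with_random_blocks(self, blocks: Sequence[RandomEffectsBlock]) -> "GrowthModelSpec":
        return GrowthModelSpec(self.name, self.base_terms, tuple(blocks), self.label_moderation)


def count_parameters(spec: GrowthModelSpec) -> int:
    """Total estimated parameters: fixed effects + covariance parameters + residual.

    Full-covariance blocks of q terms contribute q(q+1)/2 parameters,
    diagonal blocks q; the residual variance adds one.
    """
    return spec.n_fixed + sum(b.n_cov_params for b in spec.random_blocks) + 1


@dataclass
class DesignMatrices:
    """Realized fixed and random designs for a model on an observation table."""

    X: np.ndarray                      # n_obs x p fixed design
    col_names: list[str]
    blocks: list[dict] = field(default_factory=list)
    # each block dict: spec (RandomEffectsBlock), Z (sparse n x q*n_levels,
    # level-major), levels (array of group identifiers)
    y: np.ndarray | None = None
    obs_index: pd.Index | None = None

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table's invariants and return it with derived columns.

    Adds ``age_c`` (age centred at 13), numeric factor codes and label
    indicators.  Raises on duplicated design cells, unknown factor levels or
    non-finite responses.
    """
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table is missing columns: {missing}")
    obs = obs.copy()

    bad_dom = set(obs["domain"].unique()) - set(DOMAIN_CODE)
    if bad_dom:
        raise ValueError(f"unknown domain levels {sorted(bad_dom)}; valid: {sorted(DOMAIN_CODE)}")
    bad_tar = set(obs["target"].unique()) - set(TARGET_CODE)
    if bad_tar:
        raise ValueError(f"unknown target levels {sorted(bad_tar)}; valid: {sorted(TARGET_CODE)}")
    bad_lab = set(obs["parcel_label"].unique()) - set(PARCEL_LABELS)
    if bad_lab:
        raise ValueError(f"unknown parcel labels {sorted(bad_lab)}; valid: {list(PARCEL_LABELS)}")

    key = ["participant_id", "wave", "domain", "target", "parcel_id"]
    if obs.duplicated(subset=key).any():
        n_dup = int(obs.duplicated(subset=key).sum())
        raise ValueError(f"{n_dup} duplicated (participant, wave, domain, target, parcel) rows")

    if not np.all(np.isfinite(obs["bold"].to_numpy(dtype=float))):
        raise ValueError("non-finite BOLD values in observation table")
    if not np.all(np.isfinite(obs["age"].to_numpy(dtype=float))):
        raise ValueError("non-finite ages in observation table")

    obs["age_c"] = center_age(obs["age"].to_numpy(dtype=float))
    obs["domain_code"] = obs["domain"].map(DOMAIN_CODE).astype(float)
    obs["target_code"] = obs["target"].map(TARGET_CODE).astype(float)
    obs["label_self"] = (obs["parcel_label"] == "self").astype(float)
    obs["label_social"] = (obs["parcel_label"] == "social").astype(float)
    return obs


def _term_values(obs: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Product regressor for one growth term, evaluated per observation."""
    cols = {
        "age": obs["age_c"].to_numpy(),
        "age2": obs["age_c"].to_numpy() ** 2,
        "domain": obs["domain_code"].to_numpy(),
        "target": obs["target_code"].to_numpy(),
    }
    v = np.ones(len(obs))
    for tok in term:
        if tok not in cols:
            raise ValueError(f"term references unknown covariate {tok!r}")
        v = v * cols[tok]
    return v


def build_design(obs: pd.DataFrame, spec: GrowthModelSpec) -> DesignMatrices:
    """Construct fixed and random design matrices for a growth model.

    The fixed matrix has one control/reference column per base term plus the
    term crossed with the self and social parcel indicators.  Each random
    block yields a sparse incidence-times-covariate matrix in level-major
    column order (all q terms of level 1, then level 2, ...).
    """
    if len(obs) == 0:
        raise ValueError("observation table is empty")
    if "age_c" not in obs.columns:
        obs = validate_observations(obs)

    n = len(obs)
    cols, names = [], []
    for t in spec.base_terms:
        v = _term_values(obs, t)
        cols.append(v)
        names.append(gamma_name(t, "control"))
        if spec.label_moderation:
            cols.append(v * obs["label_self"].to_numpy())
            names.append(gamma_name(t, "self"))
            cols.append(v * obs["label_social"].to_numpy())
            names.append(gamma_name(t, "social"))
    X = np.column_stack(cols)

    blocks = []
    for blk in spec.random_blocks:
        group_col = "participant_id" if blk.grouping == "participant" else "parcel_id"
        codes, levels = pd.factorize(obs[group_col], sort=True)
        q = blk.q
        rows = np.tile(np.arange(n), q)
        cols_idx = np.concatenate([codes * q + j for j in range(q)])
        data = np.concatenate([_term_values(obs, t) for t in blk.terms])
        Z = sparse.coo_matrix(
            (data, (rows, cols_idx)), shape=(n, q * len(levels))
        ).tocsr()
        blocks.append({"spec": blk, "Z": Z, "levels": np.asarray(levels)})

    y = obs["bold"].to_numpy(dtype=float) if "bold" in obs.columns else None
    return DesignMatrices(X=X, col_names=names, blocks=blocks, y=y, obs_index=obs.index)


def decode_design(X: np.ndarray, col_names: list[str]) -> pd.DataFrame:
    """Recover factor levels and centred age from coded design columns.

    Inverse of the coding used by :func:`build_design`; requires the age,
    domain and target main-effect columns to be present.
    """
    ix = {n: i for i, n in enumerate(col_names)}
    need = ["gamma_100", "gamma_300", "gamma_600"]
    for nm in need:
        if nm not in ix:
            raise ValueError(f"cannot decode: column {nm} absent")
    age_c = X[:, ix["gamma_100"]]
    domain = np.where(X[:, ix["gamma_300"]] > 0, "Social", "Academic")
    target = np.where(X[:, ix["gamma_600"]] > 0, "Self", "Other")
    label = np.full(X.shape[0], "control", dtype=object)
    if "gamma_001.self" in ix:
        label[X[:, ix["gamma_001.self"]] == 1.0] = "self"
        label[X[:, ix["gamma_001.soc"]] == 1.0] = "social"
    return pd.DataFrame({"age_c": age_c, "domain": domain, "target": target,
                         "parcel_label": label})


def read_observations(path) -> pd.DataFrame:
    """Read a tab-separated observation table (UTF-8, '.' decimal)."""
    obs = pd.read_csv(path, sep="\t")
    return validate_observations(obs)


def write_observations(obs: pd.DataFrame, path) -> None:
    obs.loc[:, list(OBSERVATION_COLUMNS)].to_csv(path, sep="\t", index=False)
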