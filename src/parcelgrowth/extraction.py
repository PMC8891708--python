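"""Parcel-level signal extraction and harmonization.

Turns per-session 3D contrast images plus an integer-labelled parcellation
atlas into a long table of parcel means, then harmonizes them: each
parcel's values are divided by that parcel's standard deviation across all
sessions and conditions (no mean-centring), and observations more than
z standard deviations from the grand mean of the standardized values are
excluded.  No resampling is performed anywhere: image and atlas must sit on
the identical voxel grid, and a mismatch is an error, never a silent
interpolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .design import DOMAIN_CODE, PARCEL_LABELS, TARGET_CODE, validate_observations

log = logging.getLogger(__name__)

__all__ = [
    "ParcelAtlas", "validate_alignment", "extract_parcel_means",
    "standardize_within_parcel", "exclude_outliers", "assemble_observations",
    "read_label_table",
]


@dataclass
class ParcelAtlas:
    """Integer-labelled parcellation volume; 0 is background."""

    labels: np.ndarray
    affine: np.ndarray
    zooms: tuple

    @classmethod
    def from_image(cls, img) -> "ParcelAtlas":
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            img = nib.load(str(img))
        data = np.asarray(img.dataobj)
        labels = np.rint(data).astype(np.int64)
        if not np.allclose(data, labels, atol=1e-6):
            raise ValueError("atlas volume contains non-integer labels")
        return cls(labels=labels, affine=np.asarray(img.affine),
                   zooms=tuple(float(z) for z in img.header.get_zooms()[:3]))

    @property
    def parcel_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    @property
    def shape(self):
        return self.labels.shape


def _grid_of(img):
    if isinstance(img, ParcelAtlas):
        return img.shape, img.zooms, img.affine
    if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
        img = nib.load(str(img))
    return (img.shape[:3], tuple(float(z) for z in img.header.get_zooms()[:3]),
            np.asarray(img.affine))


def validate_alignment(image, atlas) -> dict:
    """Require image and atlas to share an identical voxel grid.

    Checks shape, voxel size and affine; raises naming the first differing
    attribute.  Returns a report dict when the grids match.
    """
    ishape, izooms, iaff = _grid_of(image)
    ashape, azooms, aaff = _grid_of(atlas)
    if tuple(ishape) != tuple(ashape):
        raise ValueError(f"grid mismatch on shape: image {tuple(ishape)} vs atlas {tuple(ashape)}")
    if not np.allclose(izooms, azooms, rtol=0, atol=1e-6):
        raise ValueError(f"grid mismatch on voxel size: image {izooms} vs atlas {azooms}")
    if not np.allclose(iaff, aaff, rtol=0, atol=1e-6):
        raise ValueError("grid mismatch on affine orientation")
    return {"ok": True, "shape": tuple(ishape), "zooms": tuple(izooms)}


def extract_parcel_means(image, atlas: ParcelAtlas) -> pd.DataFrame:
    """Arithmetic mean of image values within each atlas parcel.

    Non-finite voxels are dropped from both numerator and denominator; a
    parcel with no finite voxels yields NaN and a logged warning.  Returns a
    frame with columns (parcel_id, raw_mean, n_voxels).
    """
    if not isinstance(atlas, ParcelAtlas):
        atlas = ParcelAtlas.from_image(atlas)
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = nib.load(str(image))
    if hasattr(image, "dataobj"):
        validate_alignment(image, atlas)
        data = np.asarray(image.dataobj, dtype=float)
    else:
        data = np.asarray(image, dtype=float)
        if data.shape != atlas.shape:
            raise ValueError(f"grid mismatch on shape: image {data.shape} vs atlas {atlas.shape}")

    labels = atlas.labels.ravel()
    vals = data.ravel()
    finite = np.isfinite(vals) & (labels != 0)
    nmax = int(labels.max()) + 1
    sums = np.bincount(labels[finite], weights=vals[finite], minlength=nmax)
    counts = np.bincount(labels[finite], minlength=nmax)
    ids = atlas.parcel_ids
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums[ids] / counts[ids]
    empty = counts[ids] == 0
    if empty.any():
        log.warning("parcels with no finite voxels: %s", ids[empty].tolist())
    return pd.DataFrame({"parcel_id": ids, "raw_mean": means,
                         "n_voxels": counts[ids]})


def standardize_within_parcel(estimates: pd.DataFrame, value_col: str = "raw_mean",
                              pooling: str = "parcel") -> pd.DataFrame:
    """Divide each parcel's values by their standard deviation (no centring).

    The divisor is the sample SD (n-1) pooled over all sessions and
    conditions of the parcel (``pooling='parcel'``), or computed within each
    (parcel, wave, domain, target) cell across participants
    (``pooling='cell'``).  Parcels (or cells) with zero or undefined SD are
    excluded with a warning.  Adds a ``std_value`` column.
    """
    if pooling == "parcel":
        keys = ["parcel_id"]
    elif pooling == "cell":
        keys = [k for k in ("parcel_id", "wave", "domain", "target")
                if k in estimates.columns]
    else:
        raise ValueError(f"pooling must be 'parcel' or 'cell', got {pooling!r}")

    est = estimates.copy()
    sd = est.groupby(keys)[value_col].transform(lambda v: v.std(ddof=1))
    bad = ~np.isfinite(sd) | (sd == 0)
    if bad.any():
        dropped = est.loc[bad, "parcel_id"].unique().tolist()
        warnings.warn(f"excluding {int(bad.sum())} values with zero/undefined "
                      f"within-parcel SD (parcels {dropped})")
    est = est.loc[~bad].copy()
    est["std_value"] = est[value_col] / sd[~bad]
    return est


def exclude_outliers(estimates: pd.DataFrame, z_threshold: float = 3.0,
                     value_col: str = "std_value"):
    """Drop observations beyond z_threshold grand SDs from the grand mean.

    The grand mean and SD are computed once over all standardized
    observations; returns (retained frame, report dict with the count and
    fraction removed).
    """
    v = estimates[value_col].to_numpy(dtype=float)
    gm, gsd = float(np.mean(v)), float(np.std(v, ddof=1))
    flag = np.abs(v - gm) > z_threshold * gsd
    retained = estimates.loc[~flag].copy()
    report = {
        "n_total": int(len(v)),
        "n_excluded": int(flag.sum()),
        "fraction_excluded": float(flag.mean()),
        "z_threshold": float(z_threshold),
        "grand_mean": gm,
        "grand_sd": gsd,
    }
    return retained, report


def read_label_table(path, atlas: ParcelAtlas | None = None) -> pd.DataFrame:
    """Read a parcel-category table (TSV: parcel_id, parcel_label).

    Categories must partition the atlas parcels when an atlas is given.
    """
    tab = pd.read_csv(path, sep="\t")
    return validate_label_table(tab, atlas)


def validate_label_table(tab: pd.DataFrame, atlas: ParcelAtlas | None = None) -> pd.DataFrame:
    if not {"parcel_id", "parcel_label"} <= set(tab.columns):
        raise ValueError("label table needs columns parcel_id, parcel_label")
    bad = set(tab["parcel_label"].unique()) - set(PARCEL_LABELS)
    if bad:
        raise ValueError(f"unknown parcel categories {sorted(bad)}; valid: {list(PARCEL_LABELS)}")
    if tab["parcel_id"].duplicated().any():
        raise ValueError("duplicated parcel ids in label table")
    if atlas is not None:
        atlas_ids = set(int(i) for i in atlas.parcel_ids)
        table_ids = set(int(i) for i in tab["parcel_id"])
        if atlas_ids != table_ids:
            missing = sorted(atlas_ids - table_ids)[:10]
            extra = sorted(table_ids - atlas_ids)[:10]
            raise ValueError(f"label table does not partition the atlas parcels "
                             f"(missing {missing}, extra {extra})")
    return tab


def assemble_observations(estimates: pd.DataFrame, labels: pd.DataFrame,
                          demographics: pd.DataFrame) -> pd.DataFrame:
    """Join retained parcel estimates to parcel categories and session ages.

    ``estimates`` must carry participant_id, wave, domain, target,
    parcel_id, std_value; ``demographics`` participant_id, wave, age.
    Unlabelled parcels or sessions without an age are an error listing the
    offenders.  Returns a validated long observation table.
    """
    labels = validate_label_table(labels)
    unlabelled = sorted(set(estimates["parcel_id"]) - set(labels["parcel_id"]))
    if unlabelled:
        raise ValueError(f"parcels without a category: {unlabelled[:20]}")
    demo_keys = demographics.set_index(["participant_id", "wave"])
    est_keys = set(map(tuple, estimates[["participant_id", "wave"]].drop_duplicates().values))
    missing_age = sorted(est_keys - set(demo_keys.index))
    if missing_age:
        raise ValueError(f"sessions without an age: {missing_age[:20]}")

    obs = (estimates
           .merge(labels[["parcel_id", "parcel_label"]], on="parcel_id", how="left")
           .merge(demographics[["participant_id", "wave", "age"]],
                  on=["participant_id", "wave"], how="left"))
    obs = obs.rename(columns={"std_value": "bold"})
    cols = ["participant_id", "wave", "age", "domain", "target",
            "parcel_id", "parcel_label", "bold"]
    return validate_observations(obs[cols])


def write_exclusion_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
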