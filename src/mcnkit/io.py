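"""Tabular data model and validated readers/writers for cohort files.

Two delimited-text inputs describe a cohort:

* volumes file — ``subject_id, age_scan1_weeks, age_scan2_weeks`` followed
  by ``{roi}_t1`` and ``{roi}_t2`` for every atlas ROI (volumes in mm^3);
* covariates file — ``subject_id`` plus the nine clinical covariates used
  for adjustment.

Subjects are aligned across the two files by exact string identifier,
independent of row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .errors import AlignmentError, SchemaError, ValidationError

#: Covariate columns in canonical order (besides subject_id).
COVARIATE_COLUMNS = (
    "gender",
    "total_brain_volume_mm3",
    "gestational_age_weeks",
    "age_scan1_weeks",
    "age_scan2_weeks",
    "ivh",
    "surgeries",
    "prenatal_steroids",
    "postnatal_steroids",
    "morphine_days",
)

STRESS_COLUMNS = ("procedure_count", "nicu_days")


def volume_columns(atlas: NetworkAtlas) -> list[str]:
    cols = ["subject_id", "age_scan1_weeks", "age_scan2_weeks"]
    for roi in atlas.rois:
        cols.append(f"{roi}_t1")
    for roi in atlas.rois:
        cols.append(f"{roi}_t2")
    return cols


@dataclass(frozen=True)
class LongitudinalVolumes:
    """Per-subject ROI volumes at two scans plus scan ages (weeks).

    ``data`` is wide: one row per subject, indexed by ``subject_id``, with
    ``age_scan1_weeks``, ``age_scan2_weeks`` and ``{roi}_t1`` / ``{roi}_t2``
    columns in atlas order.
    """

    data: pd.DataFrame
    atlas: NetworkAtlas

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def volumes(self, timepoint: int) -> pd.DataFrame:
        """Subjects x ROIs volume matrix for scan 1 or scan 2."""
        if timepoint not in (1, 2):
            raise ValidationError("timepoint must be 1 or 2")
        cols = [f"{roi}_t{timepoint}" for roi in self.atlas.rois]
        out = self.data[cols].copy()
        out.columns = list(self.atlas.rois)
        return out

    def scan_ages(self) -> pd.DataFrame:
        return self.data[["age_scan1_weeks", "age_scan2_weeks"]]


@dataclass(frozen=True)
class CovariateTable:
    """Per-subject clinical covariates, one row per subject, no missing values."""

    data: pd.DataFrame

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    def design_columns(self) -> pd.DataFrame:
        return self.data[list(COVARIATE_COLUMNS)]


def _validate_volumes(df: pd.DataFrame, atlas: NetworkAtlas) -> pd.DataFrame:
    expected = volume_columns(atlas)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"volumes file missing column(s): {missing}")
    df = df[expected].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s) in volumes file: {dups}")
    df = df.set_index("subject_id")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing values in volumes file for subject(s): {bad}")
    vol_cols = [c for c in df.columns if c.endswith(("_t1", "_t2"))]
    nonpos = df.index[(df[vol_cols] <= 0).any(axis=1)].tolist()
    if nonpos:
        raise ValidationError(f"non-positive volume(s) for subject(s): {nonpos}")
    bad_age = df.index[df["age_scan2_weeks"] <= df["age_scan1_weeks"]].tolist()
    if bad_age:
        raise ValidationError(
            f"age_scan2_weeks must exceed age_scan1_weeks; violated by subject(s): {bad_age}"
        )
    return df


def _validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    expected = ["subject_id", *COVARIATE_COLUMNS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"covariates file missing column(s): {missing}")
    df = df[expected].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s) in covariates file: {dups}")
    df = df.set_index("subject_id")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValidationError(f"missing covariate values for subject(s): {bad}")
    if (df["morphine_days"] < 0).any():
        bad = df.index[df["morphine_days"] < 0].tolist()
        raise ValidationError(f"negative morphine_days for subject(s): {bad}")
    return df.astype(float)


def load_cohort(
    volumes_path, covariates_path, atlas: NetworkAtlas | None = None
) -> tuple[LongitudinalVolumes, CovariateTable]:
    """Read, validate and subject-align the two cohort tables.

    Raises :class:`SchemaError` for missing columns, :class:`AlignmentError`
    when the subject sets differ, and :class:`ValidationError` for
    non-positive volumes, non-increasing scan ages or missing values.
    """
    atlas = atlas or NetworkAtlas.default()
    vols = _validate_volumes(pd.read_csv(volumes_path), atlas)
    covs = _validate_covariates(pd.read_csv(covariates_path))
    only_v = set(vols.index) - set(covs.index)
    only_c = set(covs.index) - set(vols.index)
    if only_v or only_c:
        raise AlignmentError(
            f"subjects only in volumes file: {sorted(only_v)}; "
            f"only in covariates file: {sorted(only_c)}"
        )
    order = sorted(vols.index)
    vols = vols.loc[order]
    covs = covs.loc[order]
    if not np.allclose(
        vols[["age_scan1_weeks", "age_scan2_weeks"]].astype(float),
        covs[["age_scan1_weeks", "age_scan2_weeks"]],
    ):
        raise ValidationError("scan ages disagree between volumes and covariates files")
    return LongitudinalVolumes(data=vols, atlas=atlas), CovariateTable(data=covs)


def write_cohort(
    volumes: LongitudinalVolumes, covariates: CovariateTable, volumes_path, covariates_path
) -> None:
    """Write the two cohort tables in the documented schema (round-trip safe)."""
    volumes.data.reset_index().to_csv(volumes_path, index=False)
    covariates.data.reset_index().to_csv(covariates_path, index=False)


def load_stress_table(path) -> pd.DataFrame:
    """Read the invasive-procedures table: subject_id, procedure_count, nicu_days."""
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", *STRESS_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"stress file missing column(s): {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df.set_index("subject_id")
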