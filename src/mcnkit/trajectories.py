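"""Volume trajectories: annualized growth rates and covariate adjustment.

The growth rate of an ROI is the volume change between the two scans,
normalized on the first-scan volume and divided by the inter-scan interval
in weeks:

    rate = ((v2 - v1) / v1) / (age2 - age1)     [fraction per week]

Covariate effects (gender, total brain volume, gestational age at birth,
both scan ages, intraventricular hemorrhage, surgeries, pre-/postnatal
corticosteroids, days of morphine) are removed per ROI by ordinary least
squares; the externally (leave-one-out) studentized residuals are what the
covariance networks are built from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import COVARIATE_COLUMNS, CovariateTable, LongitudinalVolumes


def annualized_rate(v1, v2, age1, age2):
    """Normalized weekly growth rate; vectorized over array inputs."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    age1 = np.asarray(age1, dtype=float)
    age2 = np.asarray(age2, dtype=float)
    if (v1 <= 0).any():
        raise ValidationError("baseline volume must be strictly positive")
    if (age2 <= age1).any():
        raise ValidationError("age at scan 2 must exceed age at scan 1")
    out = ((v2 - v1) / v1) / (age2 - age1)
    return float(out) if out.ndim == 0 else out


def compute_rates(volumes: LongitudinalVolumes) -> pd.DataFrame:
    """Subjects x ROIs matrix of raw weekly growth rates."""
    v1 = volumes.volumes(1).to_numpy()
    v2 = volumes.volumes(2).to_numpy()
    ages = volumes.scan_ages().to_numpy()
    rates = annualized_rate(v1, v2, ages[:, [0]], ages[:, [1]])
    return pd.DataFrame(rates, index=volumes.subjects, columns=list(volumes.atlas.rois))


def design_matrix(covariates: CovariateTable) -> pd.DataFrame:
    """Intercept plus the covariate columns, in canonical order."""
    X = covariates.design_columns().astype(float).copy()
    X.insert(0, "intercept", 1.0)
    return X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose removal restores full relative rank
        collinear = []
        for k in range(X.shape[1]):
            sub = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[k])
        raise ValidationError(f"design matrix is rank-deficient; collinear column(s): {collinear}")


def studentize(
    Y: np.ndarray, X: np.ndarray, kind: str = "external", subject_ids=None
) -> np.ndarray:
    """OLS residuals of every column of Y on X, studentized.

    ``kind='external'`` gives leave-one-out studentized residuals
    t_i = e_i / (s_(-i) * sqrt(1 - h_ii)), computed in closed form from the
    hat diagonal (no refits); ``kind='internal'`` divides by the overall
    residual SD instead; ``kind='raw'`` returns the plain OLS residuals.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if kind not in ("external", "internal", "raw"):
        raise ValidationError(f"unknown studentization kind {kind!r}")
    if kind == "external" and n <= p + 1:
        raise ValidationError(f"need n > p + 1 subjects for external studentization (n={n}, p={p})")
    Q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", Q, Q)  # leverage = diag of the hat matrix
    close_one = np.nonzero(h >= 1 - 1e-10)[0]
    if close_one.size:
        who = (
            [subject_ids[i] for i in close_one] if subject_ids is not None else close_one.tolist()
        )
        raise ValidationError(f"leverage equals 1 for subject(s) {who}; residual undefined")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta
    if kind == "raw":
        return E
    sse = (E**2).sum(axis=0)
    if kind == "internal":
        s2 = sse / (n - p)
        return E / np.sqrt(s2[None, :] * (1 - h)[:, None])
    # external: s^2_(-i) = (SSE - e_i^2/(1-h_i)) / (n - p - 1)
    s2_loo = (sse[None, :] - E**2 / (1 - h)[:, None]) / (n - p - 1)
    s2_loo = np.maximum(s2_loo, np.finfo(float).tiny)
    return E / np.sqrt(s2_loo * (1 - h)[:, None])


def residualize(
    rates: pd.DataFrame, covariates: CovariateTable, kind: str = "external"
) -> pd.DataFrame:
    """Remove covariate effects from every ROI rate column.

    Subjects must match between ``rates`` and ``covariates``. Returns the
    studentized residual matrix with the same index/columns.
    """
    if not rates.index.equals(covariates.data.index):
        cov = covariates.data.reindex(rates.index)
        if cov.isna().any().any():
            raise ValidationError("rates and covariates cover different subjects")
        covariates = CovariateTable(data=cov)
    Xdf = design_matrix(covariates)
    X = Xdf.to_numpy()
    _check_rank(X, list(Xdf.columns))
    T = studentize(rates.to_numpy(), X, kind=kind, subject_ids=list(rates.index))
    return pd.DataFrame(T, index=rates.index, columns=rates.columns)


def prepare_rates(
    volumes: LongitudinalVolumes,
    covariates: CovariateTable,
    order: str = "rates_then_residualize",
    kind: str = "external",
) -> pd.DataFrame:
    """End-to-end: volumes -> studentized growth-rate matrix.

    The default computes rates first and then residualizes them ("studentized
    trajectory"). The alternative order (``order='residualize_volumes'``)
    studentizes each timepoint's volumes on the covariates and takes the
    per-week difference of the two studentized maps; it exists as a
    documented switch because the two orders are not identical.
    """
    if order == "rates_then_residualize":
        return residualize(compute_rates(volumes), covariates, kind=kind)
    if order == "residualize_volumes":
        Xdf = design_matrix(covariates)
        X = Xdf.to_numpy()
        _check_rank(X, list(Xdf.columns))
        sids = list(volumes.subjects)
        z1 = studentize(volumes.volumes(1).to_numpy(), X, kind=kind, subject_ids=sids)
        z2 = studentize(volumes.volumes(2).to_numpy(), X, kind=kind, subject_ids=sids)
        ages = volumes.scan_ages().to_numpy()
        dt = (ages[:, 1] - ages[:, 0])[:, None]
        return pd.DataFrame(
            (z2 - z1) / dt, index=volumes.subjects, columns=list(volumes.atlas.rois)
        )
    raise ValidationError(f"unknown order {order!r}")
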