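"""Group-level maturational covariance association matrices.

An association matrix is the across-subject Pearson correlation of
studentized growth rates between every pair of ROIs, with the diagonal set
to zero, plus its Fisher z-transform (atanh). High correlation between two
regions means their gray-matter volumes matured at similar rates across
the group — "maturational coupling".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import NetworkAtlas
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/- (1 - 1e-7) before atanh inside permutation
#: loops, so degenerate draws in tiny synthetic fixtures cannot produce
#: infinite z. Never triggered at realistic sample sizes.
R_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher's variance-stabilizing z-transform, atanh(r); |r| must be < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValidationError("fisher_z requires |r| < 1; clip perfect correlations first")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def correlation_matrix(X: np.ndarray, clip: bool = True) -> np.ndarray:
    """Column-wise Pearson correlation with zero diagonal.

    With ``clip=True`` (the permutation-loop convention) perfect
    correlations are clipped to +/-R_CLIP and undefined correlations from
    constant columns are set to 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    if clip:
        r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
        r = np.clip(r, -R_CLIP, R_CLIP)
    np.fill_diagonal(r, 0.0)
    return r


@dataclass(frozen=True)
class AssociationMatrix:
    """Pearson (r) and Fisher-z association matrices for one group."""

    r: np.ndarray
    z: np.ndarray
    rois: tuple[str, ...]
    group: str
    n_subjects: int

    def __post_init__(self) -> None:
        k = len(self.rois)
        if self.r.shape != (k, k):
            raise ValidationError(f"association matrix must be {k}x{k}")
        if not np.allclose(self.r, self.r.T):
            raise ValidationError("association matrix must be symmetric")
        if np.abs(np.diag(self.r)).max() != 0.0:
            raise ValidationError("association matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.rois), columns=list(self.rois))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str, n_subjects: int) -> "AssociationMatrix":
        r = df.to_numpy(dtype=float)
        np.fill_diagonal(r, 0.0)
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        np.fill_diagonal(z, 0.0)
        return cls(r=r, z=z, rois=tuple(df.columns), group=group, n_subjects=n_subjects)


def build_mcn(
    rates: pd.DataFrame,
    subjects=None,
    group: str = "",
    atlas: NetworkAtlas | None = None,
) -> AssociationMatrix:
    """Build the group's association matrix from studentized rates.

    ``subjects`` selects a subset of the rate-matrix rows (boolean mask or
    list of identifiers); at least 4 subjects are required and no ROI column
    may be constant over the subset.
    """
    sub = rates if subjects is None else rates.loc[subjects]
    n = len(sub)
    if n < 4:
        raise ValidationError(f"need >= 4 subjects to build an association matrix, got {n}")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(sub.columns, sd) if s == 0]
        raise ValidationError(f"zero-variance ROI column(s): {bad}")
    r = correlation_matrix(X, clip=False)
    clipped = np.abs(r) >= 1
    np.fill_diagonal(clipped, False)
    if clipped.any():
        logger.warning(
            "clipping %d perfect correlation(s) to +/-%s before atanh", clipped.sum(), R_CLIP
        )
        r = np.clip(r, -R_CLIP, R_CLIP)
        np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    if atlas is not None and tuple(sub.columns) != atlas.rois:
        raise ValidationError("rate-matrix columns do not match atlas ROI order")
    return AssociationMatrix(
        r=r, z=z, rois=tuple(sub.columns), group=group, n_subjects=n
    )
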