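"""Edge-wise comparison of two groups' association matrices.

Each ROI pair's correlations are compared with the independent-samples
Fisher r-to-z statistic

    Z = (atanh(r_high) - atanh(r_low)) / sqrt(1/(n_high - 3) + 1/(n_low - 3))

with a two-sided normal p and BH-FDR over the included edges. Edges whose
correlation magnitude is below ``r_min`` (default 0.10) in BOTH groups are
treated as spurious and excluded before transformation; requiring both
groups keeps edges that are strong in one group but collapsed in the other
— exactly the decoupling pattern of interest. ``mode='either'`` excludes
when either group falls below the threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NetworkAtlas, edge_universe
from .covariance import AssociationMatrix, R_CLIP
from .errors import ValidationError
from .inference import fdr_adjust


def fisher_z_test(r_low, r_high, n_low: int, n_high: int):
    """Z statistic and two-sided p for two independent correlations."""
    if n_low <= 3 or n_high <= 3:
        raise ValidationError("both groups need n > 3 for the Fisher r-to-z test")
    zl = np.arctanh(np.clip(np.asarray(r_low, dtype=float), -R_CLIP, R_CLIP))
    zh = np.arctanh(np.clip(np.asarray(r_high, dtype=float), -R_CLIP, R_CLIP))
    se = np.sqrt(1.0 / (n_high - 3) + 1.0 / (n_low - 3))
    Z = (zh - zl) / se
    p = 2.0 * stats.norm.sf(np.abs(Z))
    return Z, p


def compare_edge_correlations(
    mcn_low: AssociationMatrix,
    mcn_high: AssociationMatrix,
    r_min: float = 0.10,
    mode: str = "both",
    atlas: NetworkAtlas | None = None,
) -> pd.DataFrame:
    """Compare every edge of the two groups' matrices.

    Returns one row per ROI pair with columns ``roi_i, roi_j, block, r_low,
    r_high, n_low, n_high, z_stat, p, q, excluded, exclude_reason``;
    excluded edges carry NaN statistics.
    """
    if mcn_low.rois != mcn_high.rois:
        raise ValidationError("the two association matrices cover different ROIs")
    if mode not in ("both", "either"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    if atlas is not None and atlas.rois != mcn_low.rois:
        raise ValidationError("atlas does not match the association matrices")
    if atlas is None:
        atlas = NetworkAtlas(
            rois=mcn_low.rois,
            hemisphere=tuple("left" for _ in mcn_low.rois),
            network=tuple("SN" for _ in mcn_low.rois),
            strict=False,
        )
        uni = edge_universe(atlas)
        uni["block"] = ""
    else:
        uni = edge_universe(atlas)

    rl = mcn_low.r[uni["i"], uni["j"]]
    rh = mcn_high.r[uni["i"], uni["j"]]
    below_low = np.abs(rl) < r_min
    below_high = np.abs(rh) < r_min
    excluded = (below_low & below_high) if mode == "both" else (below_low | below_high)
    reason = np.where(
        excluded,
        f"|r| < {r_min} in {'both groups' if mode == 'both' else 'at least one group'}",
        "",
    )

    Z = np.full(len(uni), np.nan)
    p = np.full(len(uni), np.nan)
    inc = ~excluded
    if inc.any():
        Z[inc], p[inc] = fisher_z_test(
            rl[inc], rh[inc], mcn_low.n_subjects, mcn_high.n_subjects
        )
    q = np.full(len(uni), np.nan)
    if inc.any():
        q[inc] = fdr_adjust(np.maximum(p[inc], np.finfo(float).tiny))

    return pd.DataFrame(
        {
            "roi_i": uni["roi_i"],
            "roi_j": uni["roi_j"],
            "block": uni["block"],
            "r_low": rl,
            "r_high": rh,
            "n_low": mcn_low.n_subjects,
            "n_high": mcn_high.n_subjects,
            "z_stat": Z,
            "p": p,
            "q": q,
            "excluded": excluded,
            "exclude_reason": reason,
        }
    )
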