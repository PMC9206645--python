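"""Network-level comparison: density thresholding, coupling counts,
label-permutation inference and FDR correction.

Both groups' association matrices are binarized at the same density K —
the top ``m = round(K * n_pairs)`` edges by Fisher z (signed, strongest
positive first) are retained — so retained-edge counts per network block
are directly comparable. The group difference per block,
``delta = count_high - count_low``, is tested against a permutation null
built by reshuffling group labels and re-running the entire
build-threshold-count pipeline. Because both groups keep exactly m edges,
the six block deltas always sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .atlas import BLOCKS, NetworkAtlas, block_sizes, edge_universe
from .covariance import AssociationMatrix, correlation_matrix
from .errors import ValidationError


def m_from_density(K: float, n_pairs: int) -> int:
    """Retained-edge count at density K: half-up rounding of K * n_pairs."""
    if not 0 < K <= 1:
        raise ValidationError(f"density K must be in (0, 1], got {K}")
    return int(np.floor(K * n_pairs + 0.5))


def default_density_grid() -> np.ndarray:
    """The reporting sweep: 0.10 <= K <= 0.30 in 0.01 increments."""
    return np.round(np.arange(0.10, 0.30 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class BinaryNetwork:
    """Symmetric 0/1 adjacency at a fixed edge density."""

    adjacency: np.ndarray
    density: float
    m: int
    rois: tuple[str, ...]

    def __post_init__(self) -> None:
        A = self.adjacency
        if not np.array_equal(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if np.abs(np.diag(A)).max(initial=0) != 0:
            raise ValidationError("adjacency diagonal must be zero")
        iu = np.triu_indices(A.shape[0], 1)
        if int(A[iu].sum()) != self.m:
            raise ValidationError("edge count does not match m")


@dataclass(frozen=True)
class CouplingCounts:
    """Retained-edge counts per network block; they partition the m edges."""

    counts: dict[str, int]
    m: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.m:
            raise ValidationError("block counts must sum to the retained-edge count m")

    def as_series(self) -> pd.Series:
        return pd.Series({b: self.counts.get(b, 0) for b in BLOCKS}, name="count")


class _EdgeIndex:
    """Precomputed upper-triangle indexing and block codes for one atlas."""

    def __init__(self, atlas: NetworkAtlas):
        uni = edge_universe(atlas)
        self.atlas = atlas
        self.rows = uni["i"].to_numpy()
        self.cols = uni["j"].to_numpy()
        self.codes = np.array([BLOCKS.index(b) for b in uni["block"]])
        self.n_pairs = len(uni)
        sizes = block_sizes(atlas)
        self.present_blocks = [b for b in BLOCKS if sizes[b] > 0]
        self.sizes = sizes

    def upper(self, M: np.ndarray) -> np.ndarray:
        return M[self.rows, self.cols]

    def top_m_counts(self, zvec: np.ndarray, ms: np.ndarray) -> np.ndarray:
        """Block counts of the top-m edges for each m in ms (shape len(ms) x 6).

        Edges are ranked by signed z descending; ties resolved by (i, j)
        pair order via the stable sort.
        """
        order = np.argsort(-zvec, kind="stable")
        onehot = np.zeros((self.n_pairs, len(BLOCKS)))
        onehot[np.arange(self.n_pairs), self.codes[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)
        return cum[np.asarray(ms) - 1].astype(int)


def threshold_binarize(mcn: AssociationMatrix, K: float) -> BinaryNetwork:
    """Keep the strongest m = round(K * n_pairs) edges as 1, the rest 0."""
    k = len(mcn.rois)
    n_pairs = k * (k - 1) // 2
    m = m_from_density(K, n_pairs)
    iu = np.triu_indices(k, 1)
    zvec = mcn.z[iu]
    order = np.argsort(-zvec, kind="stable")[:m]
    A = np.zeros((k, k), dtype=int)
    A[iu[0][order], iu[1][order]] = 1
    A = A + A.T
    return BinaryNetwork(adjacency=A, density=K, m=m, rois=mcn.rois)


def count_connections(net: BinaryNetwork, atlas: NetworkAtlas) -> CouplingCounts:
    """Count retained edges inside each of the six network blocks."""
    if net.rois != atlas.rois:
        raise ValidationError("binary network and atlas cover different ROIs")
    idx = _EdgeIndex(atlas)
    edge_on = idx.upper(net.adjacency).astype(bool)
    counts = np.bincount(idx.codes[edge_on], minlength=len(BLOCKS))
    for b, c in zip(BLOCKS, counts):
        if c > idx.sizes[b]:
            raise ValidationError(f"count for {b} exceeds its block size")
    return CouplingCounts(counts={b: int(c) for b, c in zip(BLOCKS, counts)}, m=net.m)


def _split_masks(labels: pd.Series, low_label: str, high_label: str) -> tuple[np.ndarray, np.ndarray]:
    vals = labels.astype(str)
    low = (vals == low_label).to_numpy()
    high = (vals == high_label).to_numpy()
    uncovered = ~(low | high)
    if uncovered.any():
        extra = sorted(set(vals[uncovered]))
        raise ValidationError(
            f"labels contain group(s) {extra} besides {low_label!r}/{high_label!r}; "
            "subset the cohort first"
        )
    if low.sum() < 4 or high.sum() < 4:
        raise ValidationError("each group needs >= 4 subjects")
    return low, high


def _delta_counts(
    X: np.ndarray, high: np.ndarray, ms: np.ndarray, idx: _EdgeIndex
) -> np.ndarray:
    """delta (high - low) block counts, shape len(ms) x 6, on raw arrays."""
    zh = np.arctanh(idx.upper(correlation_matrix(X[high])))
    zl = np.arctanh(idx.upper(correlation_matrix(X[~high])))
    return idx.top_m_counts(zh, ms) - idx.top_m_counts(zl, ms)


def coupling_delta(
    rates: pd.DataFrame,
    labels: pd.Series,
    K: float,
    atlas: NetworkAtlas | None = None,
    low_label: str = "low",
    high_label: str = "high",
) -> pd.Series:
    """Observed high-minus-low retained-edge count per block at density K.

    Positive values mean higher coupling in the high-stress group. The six
    values always sum to zero because both groups retain exactly m edges.
    """
    atlas = atlas or NetworkAtlas.default()
    idx = _EdgeIndex(atlas)
    if tuple(rates.columns) != atlas.rois:
        raise ValidationError("rate-matrix columns do not match atlas ROI order")
    low, high = _split_masks(labels.loc[rates.index], low_label, high_label)
    keep = low | high
    X = rates.to_numpy(dtype=float)[keep]
    ms = np.array([m_from_density(K, idx.n_pairs)])
    delta = _delta_counts(X, high[keep], ms, idx)[0]
    assert delta.sum() == 0, "block deltas must sum to zero at equal density"
    return pd.Series({b: int(d) for b, d in zip(BLOCKS, delta)}, name=f"delta@K={K}")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_test(
    rates: pd.DataFrame,
    labels: pd.Series,
    K_values=None,
    n_perm: int = 5000,
    seed: int | None = None,
    atlas: NetworkAtlas | None = None,
    low_label: str = "low",
    high_label: str = "high",
) -> pd.DataFrame:
    """Label-permutation test of block coupling differences across densities.

    For each permutation the group labels are reshuffled (group sizes
    preserved) and the whole pipeline — association matrix per group,
    equal-density thresholding, block counting, delta — is recomputed at
    every density. Two-tailed p per block and density uses the add-one
    smoothed rule p = (1 + #{|delta_perm| >= |delta_obs|}) / (1 + n_perm);
    the block p-values within each density are BH-FDR adjusted.

    Returns a tidy DataFrame with one row per (block, K): columns
    ``block, K, delta, p, q, perm_mean, perm_lo95, perm_hi95, n_perm, seed``.
    """
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    atlas = atlas or NetworkAtlas.default()
    idx = _EdgeIndex(atlas)
    if tuple(rates.columns) != atlas.rois:
        raise ValidationError("rate-matrix columns do not match atlas ROI order")
    K_values = np.atleast_1d(default_density_grid() if K_values is None else np.asarray(K_values, dtype=float))
    ms = np.array([m_from_density(K, idx.n_pairs) for K in K_values])

    low, high = _split_masks(labels.loc[rates.index], low_label, high_label)
    keep = low | high
    X = rates.to_numpy(dtype=float)[keep]
    high_k = high[keep]
    n_high = int(high_k.sum())
    n = X.shape[0]

    obs = _delta_counts(X, high_k, ms, idx)  # nK x 6
    assert (obs.sum(axis=1) == 0).all()

    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, len(ms), len(BLOCKS)), dtype=np.int64)
    base = np.zeros(n, dtype=bool)
    base[:n_high] = True
    for b in range(n_perm):
        perm[b] = _delta_counts(X, rng.permutation(base), ms, idx)

    exceed = (np.abs(perm) >= np.abs(obs)[None]).sum(axis=0)  # nK x 6
    p = (1.0 + exceed) / (1.0 + n_perm)
    lo, hi = np.percentile(perm, [2.5, 97.5], axis=0)
    mean = perm.mean(axis=0)

    present = [BLOCKS.index(b) for b in idx.present_blocks]
    rows = []
    for ki, K in enumerate(K_values):
        q = np.full(len(BLOCKS), np.nan)
        q[present] = fdr_adjust(p[ki, present])
        for bi, blockname in enumerate(BLOCKS):
            if bi not in present:
                continue
            rows.append(
                {
                    "block": blockname,
                    "K": float(K),
                    "delta": int(obs[ki, bi]),
                    "p": float(p[ki, bi]),
                    "q": float(q[bi]),
                    "perm_mean": float(mean[ki, bi]),
                    "perm_lo95": float(lo[ki, bi]),
                    "perm_hi95": float(hi[ki, bi]),
                    "n_perm": n_perm,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def density_sweep_report(results: pd.DataFrame, report_K: float = 0.20) -> pd.DataFrame:
    """Summarize a density sweep, flagging the reporting density.

    Adds per-block ``consistency``: the fraction of densities whose delta
    sign and significance status (q < 0.05) both match the block's values at
    ``report_K``. A block that is significant with a stable sign across the
    whole sweep scores 1.0.
    """
    at_report = np.isclose(results["K"], report_K)
    if not at_report.any():
        raise ValidationError(f"no results at report density K={report_K}")
    out = results.copy()
    out["is_report_density"] = at_report
    cons = {}
    for blockname, sub in out.groupby("block"):
        ref = sub.loc[sub["is_report_density"]].iloc[0]
        sign_match = np.sign(sub["delta"]) == np.sign(ref["delta"])
        sig_match = (sub["q"] < 0.05) == (ref["q"] < 0.05)
        cons[blockname] = float((sign_match & sig_match).mean())
    out["consistency"] = out["block"].map(cons)
    return out
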