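"""ROI atlas: node list, hemisphere and network membership, edge universe.

The default atlas covers 32 regions of interest (16 per hemisphere) drawn
from three canonical large-scale brain networks:

* salience network (SN, 12 nodes): amygdala, anterior cingulate cortex,
  insula, thalamus, subthalamic nucleus, lentiform nucleus;
* executive control network (ECN, 8 nodes): frontal lobe, parietal lobe,
  cerebellum, caudate nucleus;
* default mode network (DMN, 12 nodes): posterior cingulate gyrus,
  hippocampus, anterior/posterior parahippocampal gyrus,
  anterior/posterior fusiform.

All downstream code is atlas-generic: a smaller atlas (e.g. 6 ROIs in
tests) flows through the same paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import pandas as pd

from .errors import ValidationError

NETWORKS = ("SN", "DMN", "ECN")

#: Canonical ordering of the six network blocks (three within, three between).
BLOCKS = ("within_SN", "within_DMN", "within_ECN", "SN_DMN", "SN_ECN", "DMN_ECN")

_BETWEEN_LABEL = {
    frozenset({"SN", "DMN"}): "SN_DMN",
    frozenset({"SN", "ECN"}): "SN_ECN",
    frozenset({"DMN", "ECN"}): "DMN_ECN",
}


def block_label(net_a: str, net_b: str) -> str:
    """Canonical block label for an edge joining two networks."""
    if net_a == net_b:
        return f"within_{net_a}"
    return _BETWEEN_LABEL[frozenset({net_a, net_b})]


@dataclass(frozen=True)
class NetworkAtlas:
    """Ordered ROI list with hemisphere and network membership.

    The ROI order given at construction is the canonical order: volume
    columns, rate-matrix columns and association-matrix rows all follow it.
    """

    rois: tuple[str, ...]
    hemisphere: tuple[str, ...]
    network: tuple[str, ...]
    strict: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        n = len(self.rois)
        if len(self.hemisphere) != n or len(self.network) != n:
            raise ValidationError("rois, hemisphere and network must have equal length")
        if len(set(self.rois)) != n:
            raise ValidationError("duplicate ROI names in atlas")
        bad_nets = set(self.network) - set(NETWORKS)
        if bad_nets:
            raise ValidationError(f"unknown network label(s): {sorted(bad_nets)}")
        bad_hemi = set(self.hemisphere) - {"left", "right"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere label(s): {sorted(bad_hemi)}")
        if self.strict:
            if n != 32:
                raise ValidationError(f"strict atlas requires 32 ROIs, got {n}")
            per_hemi = pd.Series(self.hemisphere).value_counts()
            if per_hemi.get("left", 0) != 16 or per_hemi.get("right", 0) != 16:
                raise ValidationError("strict atlas requires 16 ROIs per hemisphere")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_pairs(self) -> int:
        n = self.n_rois
        return n * (n - 1) // 2

    def index_of(self, roi: str) -> int:
        return self.rois.index(roi)

    def networks_present(self) -> tuple[str, ...]:
        return tuple(n for n in NETWORKS if n in self.network)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict: bool = True) -> "NetworkAtlas":
        missing = {"roi", "hemisphere", "network"} - set(df.columns)
        if missing:
            raise ValidationError(f"atlas table missing column(s): {sorted(missing)}")
        return cls(
            rois=tuple(df["roi"].astype(str)),
            hemisphere=tuple(df["hemisphere"].astype(str)),
            network=tuple(df["network"].astype(str)),
            strict=strict,
        )

    @classmethod
    def from_csv(cls, path, strict: bool = True) -> "NetworkAtlas":
        return cls.from_frame(pd.read_csv(path), strict=strict)

    @classmethod
    def default(cls) -> "NetworkAtlas":
        """The packaged 32-ROI SN/DMN/ECN atlas."""
        with resources.files("mcnkit.data").joinpath("default_atlas.csv").open() as fh:
            return cls.from_frame(pd.read_csv(fh), strict=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi": self.rois, "hemisphere": self.hemisphere, "network": self.network}
        )


def edge_universe(atlas: NetworkAtlas) -> pd.DataFrame:
    """Enumerate all unordered ROI pairs with their network-block label.

    Pairs are listed in (i, j) atlas-index order with i < j, which is the
    deterministic canonical order used for threshold tie-breaking. Columns:
    ``i, j, roi_i, roi_j, block``.
    """
    rows = [
        (i, j, atlas.rois[i], atlas.rois[j], block_label(atlas.network[i], atlas.network[j]))
        for i, j in combinations(range(atlas.n_rois), 2)
    ]
    return pd.DataFrame(rows, columns=["i", "j", "roi_i", "roi_j", "block"])


def block_sizes(atlas: NetworkAtlas) -> dict[str, int]:
    """Number of possible edges per block; values sum to C(n, 2)."""
    counts = edge_universe(atlas)["block"].value_counts()
    return {b: int(counts.get(b, 0)) for b in BLOCKS}
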