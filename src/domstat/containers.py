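"""Core in-memory containers: peak tables and molecular dendrograms."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from skbio import TreeNode


class PeakTable:
    """Nonnegative molecules x samples intensity matrix.

    Molecules are treated as species and per-sample relative intensities
    as species abundances, so standard community-ecology machinery applies
    downstream. Zero means not detected.
    """

    def __init__(self, intensities: pd.DataFrame):
        data = intensities.astype(float)
        if (data.to_numpy() < 0).any():
            raise ValueError("peak intensities must be nonnegative")
        self.intensities = data
        self.intensities.index.name = "id"

    @property
    def molecules(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalized view p_ij = I_ij / sum_i I_ij (empty samples stay 0)."""
        totals = self.intensities.sum(axis=0)
        safe = totals.replace(0, np.nan)
        return self.intensities.div(safe, axis=1).fillna(0.0)

    def presence(self) -> pd.DataFrame:
        return (self.intensities > 0)

    def occupancy(self) -> pd.Series:
        """Fraction of samples in which each molecule is detected."""
        return self.presence().mean(axis=1)

    def filter_occupancy(self, min_occupancy: float, strict: bool = True) -> "PeakTable":
        """Keep molecules present in more than (``strict``) or at least
        ``min_occupancy`` of samples."""
        occ = self.occupancy()
        keep = occ > min_occupancy if strict else occ >= min_occupancy
        return PeakTable(self.intensities.loc[keep])

    def subset_samples(self, samples: Sequence[str]) -> "PeakTable":
        return PeakTable(self.intensities[list(samples)])

    def subset_molecules(self, molecules: Sequence[str]) -> "PeakTable":
        return PeakTable(self.intensities.loc[list(molecules)])


@dataclass
class Dendrogram:
    """Rooted ultrametric tree over molecules built by average linkage.

    ``kind`` records the distance source: MCD (molecular characteristics),
    TD (transformation network hops) or TWCD (the product combination).
    """

    linkage: np.ndarray
    ids: list[str]
    kind: str = "MCD"
    _cophenetic: pd.DataFrame | None = field(default=None, repr=False)
    _tree: TreeNode | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise ValueError("a dendrogram needs at least 2 molecules")

    @property
    def n_tips(self) -> int:
        return len(self.ids)

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Square tip-to-tip cophenetic distance matrix (cached)."""
        if self._cophenetic is None:
            dm = squareform(cophenet(self.linkage))
            self._cophenetic = pd.DataFrame(dm, index=self.ids, columns=self.ids)
        return self._cophenetic

    def to_tree(self) -> TreeNode:
        """scikit-bio tree with branch lengths consistent with the linkage heights."""
        if self._tree is None:
            self._tree = TreeNode.from_linkage_matrix(self.linkage, self.ids)
        return self._tree

    def total_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.to_tree().traverse()))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.to_tree().write(buf, format="newick")
        return buf.getvalue()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())
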