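"""Putative biochemical transformations from pairwise mass differences.

Two peaks whose exact-mass difference matches the mass of a known
chemical moiety (H2O, CO2, an amino-acid residue, a sugar, ...) are
linked by a putative transformation edge; a molecule's transformation
count (its degree in that network) proxies how biochemically active
it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .formula_core import parse_hill, MONOISOTOPIC


@dataclass(frozen=True)
class TransformationDatabase:
    """Named positive mass differences of common biochemical moieties."""

    names: tuple[str, ...]
    deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ValueError("transformation database is empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("transformation names must be unique")
        if any(d <= 0 for d in self.deltas):
            raise ValueError("mass differences must be positive")

    def __len__(self) -> int:
        return len(self.names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "mass_difference": self.deltas})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "TransformationDatabase":
        return cls(tuple(mapping.keys()), tuple(float(v) for v in mapping.values()))

    @classmethod
    def from_file(cls, path) -> "TransformationDatabase":
        """Read a two-column delimited file (name, mass_difference); '#' comments allowed."""
        table = pd.read_csv(path, sep=None, engine="python", comment="#",
                            names=["name", "mass_difference"], header=None)
        # tolerate a header row
        try:
            float(table.iloc[0, 1])
        except (TypeError, ValueError):
            table = table.iloc[1:]
        return cls(tuple(table["name"].astype(str)),
                   tuple(table["mass_difference"].astype(float)))

    @classmethod
    def default(cls) -> "TransformationDatabase":
        """The packaged default database of common moieties.

        Entries are stored as composition strings; monoisotopic mass
        differences are computed from atomic masses at load time.
        """
        path = resources.files("domstat.data") / "transformations.tsv"
        table = pd.read_csv(path, sep="\t", comment="#")
        deltas = [sum(MONOISOTOPIC[el] * k for el, k in parse_hill(f).items())
                  for f in table["composition"]]
        return cls(tuple(table["name"].astype(str)), tuple(deltas))


class TransformationNetwork:
    """Undirected molecule graph whose edges are matched mass differences."""

    def __init__(self, graph: nx.Graph, ids: Sequence[str]):
        self.graph = graph
        self.ids = list(ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def counts(self) -> pd.Series:
        """Per-molecule transformation count (= node degree; isolated nodes 0)."""
        deg = dict(self.graph.degree())
        return pd.Series([deg.get(i, 0) for i in self.ids],
                         index=pd.Index(self.ids, name="id"), name="n_transformations")

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (i, j, d["transformation"], d["delta_mass"])
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["a", "b", "transformation", "delta_mass"])


def build_transformation_network(
    masses: pd.Series | Mapping[str, float],
    database: TransformationDatabase | None = None,
    tolerance_da: float = 0.001,
    tolerance_ppm: float | None = None,
) -> TransformationNetwork:
    """Link molecule pairs whose mass difference matches a database entry.

    An edge (i, j) labelled t exists iff ``| |m_i - m_j| - delta_t | <= tol``.
    The scan sorts masses once and slides a window per database entry, which
    is output-identical to the naive all-pairs comparison but near-linear for
    realistic peak lists.

    Parameters
    ----------
    masses
        Molecule id -> exact mass (Da); must be finite and positive.
    tolerance_da
        Absolute match tolerance (Da). Default 0.001 Da suits FT-ICR accuracy.
    tolerance_ppm
        If given, overrides ``tolerance_da`` with a relative tolerance
        evaluated at the larger mass of the pair.
    """
    if database is None:
        database = TransformationDatabase.default()
    masses = pd.Series(masses, dtype=float)
    if not np.all(np.isfinite(masses)) or np.any(masses <= 0):
        raise ValueError("masses must be finite and positive")
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be positive")

    ids = masses.index.to_numpy()
    order = np.argsort(masses.to_numpy(), kind="stable")
    m = masses.to_numpy()[order]
    sorted_ids = ids[order]

    graph = nx.Graph()
    graph.add_nodes_from(masses.index)
    for name, delta in zip(database.names, database.deltas):
        if tolerance_ppm is not None:
            # widest possible window; exact per-pair check below
            tol_hi = (m + delta) * tolerance_ppm * 1e-6
        else:
            tol_hi = np.full_like(m, tolerance_da)
        lo = np.searchsorted(m, m + delta - tol_hi, side="left")
        hi = np.searchsorted(m, m + delta + tol_hi, side="right")
        for i in range(len(m)):
            for j in range(lo[i], hi[i]):
                if i == j:
                    continue
                observed = m[j] - m[i]
                tol = (tolerance_ppm * 1e-6 * max(m[i], m[j])
                       if tolerance_ppm is not None else tolerance_da)
                if abs(observed - delta) <= tol:
                    a, b = sorted_ids[i], sorted_ids[j]
                    if not graph.has_edge(a, b):
                        graph.add_edge(a, b, transformation=name, delta_mass=float(observed))
    return TransformationNetwork(graph, list(masses.index))


def build_transformation_network_naive(
    masses: pd.Series | Mapping[str, float],
    database: TransformationDatabase,
    tolerance_da: float = 0.001,
) -> TransformationNetwork:
    """Reference O(n^2) double loop; used as the oracle for the windowed scan."""
    masses = pd.Series(masses, dtype=float)
    ids = list(masses.index)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    vals = masses.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            diff = abs(vals[i] - vals[j])
            for name, delta in zip(database.names, database.deltas):
                if abs(diff - delta) <= tolerance_da:
                    if not graph.has_edge(ids[i], ids[j]):
                        graph.add_edge(ids[i], ids[j], transformation=name,
                                       delta_mass=float(diff))
    return TransformationNetwork(graph, ids)


def transformation_counts(network: TransformationNetwork) -> pd.Series:
    """Per-molecule transformation count (node degree)."""
    return network.counts()
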