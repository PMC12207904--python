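"""Delimited-text readers and writers for every table the pipeline uses.

TSV is the default dialect; CSV is accepted on read (sniffed). Molecule
ids must be consistent across files: peaks without a formula row are
rerouted to the dark-matter pool with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PeakTable


def _read(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def read_peak_table(path) -> PeakTable:
    """Read a molecules x samples intensity table (first column = id)."""
    return PeakTable(_read(path))


def write_peak_table(pt: PeakTable, path, sep: str = "\t") -> None:
    pt.intensities.to_csv(path, sep=sep)


def read_formula_table(path) -> pd.DataFrame:
    """Formula table with columns id, C, H, N, O, S, P[, mass]."""
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"id", "C", "H", "O"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"formula table missing columns {sorted(missing)}")
    if table["id"].duplicated().any():
        dupes = table["id"][table["id"].duplicated()].tolist()[:5]
        raise ValueError(f"duplicate molecule ids: {dupes}")
    for el in ("N", "S", "P"):
        if el not in table.columns:
            table[el] = 0
    return table


def write_formula_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata indexed by sample id with temperature/region/replicate."""
    meta = _read(path)
    if "temperature" not in meta.columns:
        raise ValueError("metadata needs a 'temperature' column")
    return meta


def write_metadata(meta: pd.DataFrame, path, sep: str = "\t") -> None:
    meta.to_csv(path, sep=sep)


def write_distance_matrix(dm: pd.DataFrame, path, sep: str = "\t") -> None:
    dm.to_csv(path, sep=sep)


def read_distance_matrix(path) -> pd.DataFrame:
    dm = _read(path)
    dm.columns = dm.index
    return dm


@dataclass
class TableBundle:
    peaks: PeakTable
    formulas: pd.DataFrame
    metadata: pd.DataFrame
    dark: PeakTable | None = None
    microbes: PeakTable | None = None
    rerouted: list = field(default_factory=list)


def read_tables(
    peaks_path,
    formulas_path,
    metadata_path,
    dark_path=None,
    microbes_path=None,
) -> TableBundle:
    """Read the full input set with cross-file id reconciliation.

    Molecules in the peak table without a formula row are rerouted to the
    dark-matter pool (one warning naming the count); sample-name mismatches
    between any table and the metadata raise.
    """
    peaks = read_peak_table(peaks_path)
    formulas = read_formula_table(formulas_path)
    metadata = read_metadata(metadata_path)

    unknown_samples = peaks.samples.difference(metadata.index)
    if len(unknown_samples):
        raise ValueError(f"peak-table samples missing from metadata: "
                         f"{list(unknown_samples)[:5]}")

    have_formula = peaks.molecules.intersection(formulas["id"])
    rerouted = list(peaks.molecules.difference(formulas["id"]))
    dark = read_peak_table(dark_path) if dark_path else None
    if rerouted:
        warnings.warn(f"{len(rerouted)} molecules lack formulas; rerouted to "
                      "dark matter", stacklevel=2)
        extra = peaks.intensities.loc[rerouted]
        dark = PeakTable(pd.concat([dark.intensities, extra]) if dark else extra)
        peaks = peaks.subset_molecules(have_formula)
    if dark is not None:
        bad = dark.samples.difference(metadata.index)
        if len(bad):
            raise ValueError(f"dark-matter samples missing from metadata: {list(bad)[:5]}")
    microbes = read_peak_table(microbes_path) if microbes_path else None
    if microbes is not None:
        bad = microbes.samples.difference(metadata.index)
        if len(bad):
            raise ValueError(f"microbial samples missing from metadata: {list(bad)[:5]}")
    return TableBundle(peaks=peaks, formulas=formulas, metadata=metadata,
                       dark=dark, microbes=microbes, rerouted=rerouted)


def write_bnti_table(result, path, sep: str = "\t") -> None:
    """Long-format pairwise assembly results writer."""
    result.pairs.to_csv(path, sep=sep, index=False)


def write_edge_table(network, path, sep: str = "\t") -> None:
    network.edge_table().to_csv(path, sep=sep, index=False)


def write_web(web, path, sep: str = "\t") -> None:
    web.weights.to_csv(path, sep=sep)
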