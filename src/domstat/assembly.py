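"""Null-model quantification of deterministic vs stochastic DOM assembly.

The between-assemblage mean nearest taxon distance (betaMNTD) on a
molecular dendrogram is compared against a null distribution obtained by
permuting tip labels ("randomizing dendrogram associations"). The
standardized deviation

    betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

classifies each sample pair: betaNTI > 2 indicates variable selection
(divergence), betaNTI < -2 homogeneous selection (convergence), and
|betaNTI| <= 2 stochastic assembly. Incidence-based weighting is the
default, because peak intensities do not carry the same meaning as
organismal abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Dendrogram, PeakTable

logger = logging.getLogger(__name__)

PROCESS_LABELS = ("variable_selection", "homogeneous_selection", "stochastic")


def bmntd_from_matrix(
    dist: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    w_a: np.ndarray | None = None,
    w_b: np.ndarray | None = None,
) -> float:
    """betaMNTD between two assemblages given a tip distance matrix.

    0.5 * [ sum_i w_iA min_j d_ij + sum_j w_jB min_i d_ij ] with incidence
    weights 1/S when ``w_a``/``w_b`` are omitted.
    """
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("betaMNTD needs two nonempty assemblages")
    sub = dist[np.ix_(idx_a, idx_b)]
    min_a = sub.min(axis=1)
    min_b = sub.min(axis=0)
    if w_a is None:
        term_a = min_a.mean()
    else:
        w = w_a / w_a.sum()
        term_a = float((min_a * w).sum())
    if w_b is None:
        term_b = min_b.mean()
    else:
        w = w_b / w_b.sum()
        term_b = float((min_b * w).sum())
    return 0.5 * (term_a + term_b)


def bmntd(
    peak_table: PeakTable,
    dendrogram: Dendrogram,
    sample_a: str,
    sample_b: str,
    weighted: bool = False,
) -> float:
    """betaMNTD between two samples of a peak table."""
    D = dendrogram.cophenetic_matrix()
    pos = {m: i for i, m in enumerate(D.index)}
    ra = peak_table.relative_abundance()
    out = []
    for s in (sample_a, sample_b):
        p = ra[s]
        present = p.index[p > 0]
        missing = present.difference(D.index)
        if len(missing):
            raise ValueError(f"sample {s!r} has molecules outside the dendrogram")
        idx = np.array([pos[m] for m in present], dtype=int)
        w = p[present].to_numpy() if weighted else None
        out.append((idx, w))
    (ia, wa), (ib, wb) = out
    return bmntd_from_matrix(D.to_numpy(), ia, ib, wa, wb)


def classify_process(bnti_value: float) -> str:
    """Map a betaNTI value to its assembly process (ties at +/-2 -> stochastic)."""
    if not np.isfinite(bnti_value):
        raise ValueError("betaNTI must be finite")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    return "stochastic"


@dataclass
class AssemblyResult:
    """Pairwise betaNTI table plus the per-process fractions."""

    pairs: pd.DataFrame  # sample_a, sample_b, bmntd_obs, null_mean, null_sd, bnti, process

    def process_fractions(self) -> pd.Series:
        counts = self.pairs["process"].value_counts()
        frac = counts.reindex(PROCESS_LABELS).fillna(0.0) / len(self.pairs)
        frac.name = "fraction"
        return frac


def bnti(
    peak_table: PeakTable,
    dendrogram: Dendrogram,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_null: int = 999,
    weighted: bool = False,
    seed: int | np.random.Generator = 0,
    per_pair_null: bool = False,
) -> AssemblyResult:
    """betaNTI for sample pairs with a tip-label permutation null.

    By default one tip permutation per null iteration is shared by every
    pair (fast, and the nulls stay exchangeable across pairs);
    ``per_pair_null`` redraws a permutation per pair per iteration.

    Requires ``n_null >= 99``; a degenerate null (zero spread) raises.
    Deterministic for a fixed seed.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    D = dendrogram.cophenetic_matrix()
    Dv = D.to_numpy()
    pos = {m: i for i, m in enumerate(D.index)}
    ra = peak_table.relative_abundance()
    if pairs is None:
        pairs = list(combinations(peak_table.samples, 2))

    memberships = {}
    for s in set(x for p in pairs for x in p):
        p = ra[s]
        present = p.index[p > 0]
        missing = present.difference(D.index)
        if len(missing):
            raise ValueError(f"sample {s!r} has molecules outside the dendrogram")
        idx = np.array([pos[m] for m in present], dtype=int)
        if idx.size == 0:
            raise ValueError(f"sample {s!r} is empty")
        memberships[s] = (idx, p[present].to_numpy() if weighted else None)

    n_tips = len(D.index)
    obs = np.array([
        bmntd_from_matrix(Dv, memberships[a][0], memberships[b][0],
                          memberships[a][1], memberships[b][1])
        for a, b in pairs
    ])
    nulls = np.empty((n_null, len(pairs)))
    for it in range(n_null):
        if not per_pair_null:
            perm = rng.permutation(n_tips)
        for k, (a, b) in enumerate(pairs):
            if per_pair_null:
                perm = rng.permutation(n_tips)
            ia, wa = memberships[a]
            ib, wb = memberships[b]
            nulls[it, k] = bmntd_from_matrix(Dv, perm[ia], perm[ib], wa, wb)

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    if np.any(null_sd == 0):
        bad = [pairs[k] for k in np.flatnonzero(null_sd == 0)]
        raise ValueError(
            f"degenerate null (all betaMNTD_null identical) for pairs {bad[:3]}; "
            "the assemblages or tree carry no permutable structure"
        )
    z = (obs - null_mean) / null_sd
    table = pd.DataFrame({
        "sample_a": [a for a, _ in pairs],
        "sample_b": [b for _, b in pairs],
        "bmntd_obs": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "bnti": z,
        "process": [classify_process(v) for v in z],
    })
    return AssemblyResult(pairs=table)


def assembly_by_fraction(
    peak_table: PeakTable,
    fraction_labels: pd.Series,
    dendrogram: Dendrogram,
    fractions: Sequence[str] = ("LA", "RA", "LI", "RI"),
    groups: pd.Series | None = None,
    n_null: int = 999,
    seed: int = 0,
    min_molecules: int = 2,
) -> dict[str, AssemblyResult]:
    """Incidence-based betaNTI separately for each reactivity-activity fraction.

    For each fraction, tips and samples are restricted to that fraction's
    molecules and betaNTI runs over all within-group sample pairs
    (``groups``, e.g. region; all samples form one group when omitted).
    Pairs where either sample holds fewer than ``min_molecules`` fraction
    molecules are skipped with a log entry.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, AssemblyResult] = {}
    ra = peak_table.relative_abundance()
    if groups is None:
        groups = pd.Series("all", index=peak_table.samples)
    for frac in fractions:
        mols = fraction_labels.index[fraction_labels == frac]
        mols = mols.intersection(peak_table.molecules).intersection(dendrogram.ids)
        if len(mols) < 2:
            logger.warning("fraction %s has < 2 molecules; skipped", frac)
            continue
        sub_pt = peak_table.subset_molecules(mols)
        D = dendrogram.cophenetic_matrix().loc[mols, mols]
        sub_dendro = _restricted_view(dendrogram, D)
        pairs = []
        for g in groups.unique():
            members = [s for s in peak_table.samples if groups[s] == g]
            for a, b in combinations(members, 2):
                na = int((sub_pt.intensities[a] > 0).sum())
                nb = int((sub_pt.intensities[b] > 0).sum())
                if na < min_molecules or nb < min_molecules:
                    logger.info("fraction %s pair (%s, %s) skipped: too few molecules",
                                frac, a, b)
                    continue
                pairs.append((a, b))
        if not pairs:
            logger.warning("fraction %s has no usable sample pairs", frac)
            continue
        out[frac] = bnti(sub_pt, sub_dendro, pairs=pairs, n_null=n_null,
                         weighted=False, seed=rng)
    return out


class _RestrictedDendrogram:
    """Lightweight stand-in exposing only the cophenetic view bnti needs."""

    def __init__(self, D: pd.DataFrame):
        self._D = D
        self.ids = list(D.index)

    def cophenetic_matrix(self) -> pd.DataFrame:
        return self._D


def _restricted_view(dendrogram: Dendrogram, D: pd.DataFrame) -> "_RestrictedDendrogram":
    return _RestrictedDendrogram(D)
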