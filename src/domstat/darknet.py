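"""Compositionality-aware co-occurrence networks and dark-matter effects.

SparCC-style basis correlations are estimated from log-ratio variances
T_ij = var(log(x_i/x_j)) under a sparsity assumption, with iterative
exclusion of the most strongly correlated pairs. Thresholded networks
built from known molecules only ("KK") are compared against networks
where part of the known nodes are replaced by dark-matter peaks ("DK");
the indicator of dark-matter effects is the percentage change in mean
node degree:

    iDME (%) = (mean(M_DK) / mean(M_KK) - 1) * 100

and decomposes additively into contributions of dark-dark links
(intra), dark-known links (inter) and the change in known-known links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import PeakTable


# ---------------------------------------------------------------- SparCC

def sparcc(
    abundance: pd.DataFrame,
    n_exclusion_iter: int = 20,
    exclusion_corr: float = 0.7,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Basis correlations from log-ratio variances (SparCC estimator).

    Parameters
    ----------
    abundance
        Components x samples nonnegative matrix (intensities or counts);
        closed to relative abundances internally, so only ratios matter.
    n_exclusion_iter
        Maximum rounds of excluding the single most strongly correlated
        pair (|rho| > ``exclusion_corr``) from the basis-variance system,
        which guards the sparsity assumption.
    pseudocount
        Replacement for zeros before taking logs; defaults to half the
        smallest positive relative abundance.

    The estimator is deterministic: intensities are not counts, so no
    Dirichlet resampling stage is applied.
    """
    X = abundance.to_numpy(dtype=float)
    p, n = X.shape
    if p < 4:
        raise ValueError("SparCC needs at least 4 components")
    if n < 8:
        raise ValueError("SparCC needs at least 8 samples")
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    if (X.sum(axis=1) == 0).any():
        bad = list(abundance.index[X.sum(axis=1) == 0])
        raise ValueError(f"components with all-zero abundance: {bad[:5]}")

    frac = X / X.sum(axis=0, keepdims=True)
    if pseudocount is None:
        pseudocount = frac[frac > 0].min() / 2.0
    frac = np.where(frac > 0, frac, pseudocount)
    logf = np.log(frac)

    V = np.cov(logf)                       # p x p covariance of log fractions
    d = np.diag(V)
    T = d[:, None] + d[None, :] - 2.0 * V  # variation matrix var(log xi/xj)

    M = np.ones((p, p))
    np.fill_diagonal(M, p - 1)
    t = T.sum(axis=1)
    excluded = np.zeros((p, p), dtype=bool)

    def _solve() -> tuple[np.ndarray, np.ndarray]:
        w = np.linalg.solve(M, t)
        w = np.maximum(w, 1e-12)           # basis variances must stay positive
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - T) / denom
        np.fill_diagonal(rho, 1.0)
        return w, np.clip(rho, -1.0, 1.0)

    w, rho = _solve()
    for _ in range(n_exclusion_iter):
        r = np.abs(rho.copy())
        np.fill_diagonal(r, 0.0)
        r[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= exclusion_corr:
            break
        if M[i, i] <= 2 or M[j, j] <= 2:   # keep the system solvable
            break
        excluded[i, j] = excluded[j, i] = True
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] = M[j, i] = 0
        t[i] -= T[i, j]
        t[j] -= T[i, j]
        w, rho = _solve()

    ids = abundance.index
    return pd.DataFrame(rho, index=ids, columns=ids)


def clr_pearson(abundance: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Pearson correlation on centered-log-ratio data; independent
    cross-check for the SparCC estimator's sign structure."""
    X = abundance.to_numpy(dtype=float)
    frac = X / X.sum(axis=0, keepdims=True)
    if pseudocount is None:
        pseudocount = frac[frac > 0].min() / 2.0
    logf = np.log(np.where(frac > 0, frac, pseudocount))
    clr = logf - logf.mean(axis=0, keepdims=True)
    r = np.corrcoef(clr)
    return pd.DataFrame(r, index=abundance.index, columns=abundance.index)


# ---------------------------------------------------------------- networks

@dataclass
class CorrelationNetwork:
    """Thresholded signed correlation network with known/dark node labels."""

    adjacency: pd.DataFrame          # boolean, symmetric, zero diagonal
    rho: pd.DataFrame                # full correlation matrix (same index)
    kinds: pd.Series                 # node id -> 'known' | 'dark'
    threshold: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.adjacency.index:
            g.add_node(node, kind=self.kinds[node])
        a = self.adjacency.to_numpy()
        idx = self.adjacency.index
        ii, jj = np.nonzero(np.triu(a, 1))
        for i, j in zip(ii, jj):
            g.add_edge(idx[i], idx[j], rho=float(self.rho.iat[i, j]))
        return g

    def edge_table(self) -> pd.DataFrame:
        a = self.adjacency.to_numpy()
        idx = self.adjacency.index
        ii, jj = np.nonzero(np.triu(a, 1))
        return pd.DataFrame({
            "a": idx[ii], "b": idx[jj],
            "rho": [float(self.rho.iat[i, j]) for i, j in zip(ii, jj)],
            "kind_a": self.kinds.iloc[ii].to_numpy(),
            "kind_b": self.kinds.iloc[jj].to_numpy(),
        })

    def mean_degree(self) -> float:
        n = len(self.adjacency)
        return float(self.adjacency.to_numpy().sum() / n)  # = 2E/N


def threshold_network(
    corr: pd.DataFrame,
    rho_min: float = 0.30,
    kinds: pd.Series | None = None,
) -> CorrelationNetwork:
    """Keep edges with |rho| >= rho_min; isolated nodes are retained."""
    r = corr.to_numpy()
    if r.shape[0] != r.shape[1] or not np.allclose(r, r.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    adj = np.abs(r) >= rho_min
    np.fill_diagonal(adj, False)
    if kinds is None:
        kinds = pd.Series("known", index=corr.index)
    return CorrelationNetwork(
        adjacency=pd.DataFrame(adj, index=corr.index, columns=corr.columns),
        rho=corr, kinds=kinds.loc[corr.index], threshold=rho_min,
    )


def sample_kk_dk(
    known_pool: Sequence[str],
    dark_pool: Sequence[str],
    n_nodes: int = 400,
    dark_ratio: str | float = "half",
    rng: np.random.Generator | int = 0,
) -> tuple[list[str], list[str]]:
    """Draw paired KK and DK node sets of equal size.

    KK is a random sample of known molecules; DK replaces a share of them
    (half, the observed dark:known ratio, or an explicit fraction) with
    random dark peaks, keeping DK's known subset inside KK.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    known_pool = list(known_pool)
    dark_pool = list(dark_pool)
    if dark_ratio == "half":
        n_dark = round(n_nodes / 2)
    elif dark_ratio == "observed":
        n_dark = round(n_nodes * len(dark_pool) / (len(dark_pool) + len(known_pool)))
    else:
        n_dark = round(n_nodes * float(dark_ratio))
    if n_nodes > len(known_pool):
        raise ValueError("known pool too small for requested node count")
    if n_dark > len(dark_pool):
        raise ValueError("dark pool too small for requested node count")
    kk = list(rng.choice(known_pool, size=n_nodes, replace=False))
    dk_known = list(rng.choice(kk, size=n_nodes - n_dark, replace=False))
    dk_dark = list(rng.choice(dark_pool, size=n_dark, replace=False))
    return kk, dk_known + dk_dark


# ---------------------------------------------------------------- iDME

@dataclass
class DarkMatterEffect:
    """iDME with its exact additive partition and the replicate log."""

    m_kk: float
    m_dk: float
    idme: float
    idme_intra: float
    idme_inter: float
    idme_kk_change: float
    n_replicates: int
    replicates: pd.DataFrame = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "m_kk": self.m_kk, "m_dk": self.m_dk, "idme": self.idme,
            "idme_intra": self.idme_intra, "idme_inter": self.idme_inter,
            "idme_kk_change": self.idme_kk_change,
        }


def _induced_degree(adj: np.ndarray, idx: np.ndarray) -> float:
    sub = adj[np.ix_(idx, idx)]
    return float(sub.sum() / len(idx))


def idme(
    known: PeakTable,
    dark: PeakTable,
    n_nodes: int = 400,
    n_replicates: int = 100,
    rho_min: float = 0.30,
    min_occupancy: float = 0.30,
    dark_ratio: str | float = "half",
    metric: str = "degree",
    seed: int = 0,
    corr: pd.DataFrame | None = None,
) -> DarkMatterEffect:
    """Indicator of dark-matter effects on network connectivity.

    Correlations are estimated once, globally, on the pooled known + dark
    molecules present in more than ``min_occupancy`` of samples; each
    replicate then induces the thresholded subgraph on freshly sampled KK
    and DK node sets and records mean degree (2E/N) plus the DK edge
    counts by endpoint class. iDME and its partition are computed from
    replicate means (ratio of means).
    """
    if metric != "degree":
        raise NotImplementedError("only the degree metric is currently supported")
    rng = np.random.default_rng(seed)
    known_f = known.filter_occupancy(min_occupancy, strict=True)
    dark_f = dark.filter_occupancy(min_occupancy, strict=True)
    known_ids = list(known_f.molecules)
    dark_ids = list(dark_f.molecules)
    if corr is None:
        pooled = pd.concat([known_f.intensities, dark_f.intensities])
        corr = sparcc(pooled)
    adj = np.abs(corr.to_numpy()) >= rho_min
    np.fill_diagonal(adj, False)
    pos = {m: i for i, m in enumerate(corr.index)}
    kind = np.array(["dark" if m in set(dark_ids) else "known" for m in corr.index])

    rows = []
    for rep in range(n_replicates):
        kk, dk = sample_kk_dk(known_ids, dark_ids, n_nodes=n_nodes,
                              dark_ratio=dark_ratio, rng=rng)
        kk_idx = np.array([pos[m] for m in kk])
        dk_idx = np.array([pos[m] for m in dk])
        m_kk = _induced_degree(adj, kk_idx)
        sub = adj[np.ix_(dk_idx, dk_idx)]
        is_dark = kind[dk_idx] == "dark"
        dd = sub[np.ix_(is_dark, is_dark)].sum()
        kk_links = sub[np.ix_(~is_dark, ~is_dark)].sum()
        cross = sub.sum() - dd - kk_links
        n = len(dk_idx)
        rows.append((m_kk, sub.sum() / n, dd / n, cross / n, kk_links / n))
    reps = pd.DataFrame(rows, columns=["m_kk", "m_dk", "m_dd", "m_cross", "m_kk_links"])

    mean_kk = reps["m_kk"].mean()
    if mean_kk == 0:
        raise ValueError("degenerate KK network: mean degree is zero; "
                         "lower rho_min or enlarge the pools")
    mean_dk = reps["m_dk"].mean()
    total = (mean_dk / mean_kk - 1.0) * 100.0
    intra = 100.0 * reps["m_dd"].mean() / mean_kk
    inter = 100.0 * reps["m_cross"].mean() / mean_kk
    kk_change = 100.0 * (reps["m_kk_links"].mean() - mean_kk) / mean_kk
    return DarkMatterEffect(
        m_kk=mean_kk, m_dk=mean_dk, idme=total,
        idme_intra=intra, idme_inter=inter, idme_kk_change=kk_change,
        n_replicates=n_replicates, replicates=reps,
    )


def idme_per_sample(
    known: PeakTable,
    dark: PeakTable,
    metadata: pd.DataFrame | None = None,
    average_by_temperature: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """iDME per sample: pools restricted to the molecules present in each
    focal sample; optionally averaged across temperature levels."""
    min_occ = kwargs.get("min_occupancy", 0.30)
    known_f = known.filter_occupancy(min_occ, strict=True)
    dark_f = dark.filter_occupancy(min_occ, strict=True)
    pooled = pd.concat([known_f.intensities, dark_f.intensities])
    corr = sparcc(pooled)
    rows = []
    for sample in known.samples:
        k_present = known_f.intensities.index[known_f.intensities[sample] > 0]
        d_present = dark_f.intensities.index[dark_f.intensities[sample] > 0]
        sub_kwargs = dict(kwargs)
        sub_kwargs["corr"] = corr.loc[
            k_present.append(d_present), k_present.append(d_present)
        ]
        res = idme(known_f.subset_molecules(k_present),
                   dark_f.subset_molecules(d_present), **sub_kwargs)
        rows.append({"sample": sample, **res.as_dict()})
    out = pd.DataFrame(rows).set_index("sample")
    if average_by_temperature:
        if metadata is None:
            raise ValueError("metadata required to average by temperature")
        out = out.join(metadata[["region", "temperature"]])
        out = out.groupby(["region", "temperature"]).mean(numeric_only=True)
    return out
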