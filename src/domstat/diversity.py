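"""Chemodiversity: within-assemblage diversity and between-assemblage dissimilarity.

Molecules play the role of species; per-sample relative peak intensities
play the role of abundances. Alpha diversity covers taxonomic indices
(richness, Shannon, Gini-Simpson, Pielou), trait-based functional
structure (CWM, RaoQ) and dendrogram-based indices (DD, MPD, MNTD);
beta diversity covers Jaccard, Bray-Curtis and both UniFrac flavours,
with classical PCoA for ordination.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .containers import Dendrogram, PeakTable
from .transformations import TransformationNetwork

import networkx as nx


# ---------------------------------------------------------------- taxonomic

def taxonomic_diversity(peak_table: PeakTable) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats), Gini-Simpson and Pielou evenness.

    Pielou's J = H / ln(richness) is reported missing for single-molecule
    samples; empty samples raise.
    """
    ra = peak_table.relative_abundance()
    if (peak_table.intensities.sum(axis=0) <= 0).any():
        bad = list(peak_table.samples[peak_table.intensities.sum(axis=0) <= 0])
        raise ValueError(f"empty samples: {bad}")
    rows = []
    for sample in ra.columns:
        p = ra[sample].to_numpy()
        p = p[p > 0]
        richness = p.size
        shannon = float(-(p * np.log(p)).sum())
        gini_simpson = float(1.0 - (p ** 2).sum())
        pielou = shannon / np.log(richness) if richness > 1 else np.nan
        rows.append((richness, shannon, gini_simpson, pielou))
    return pd.DataFrame(rows, index=ra.columns,
                        columns=["richness", "shannon", "gini_simpson", "pielou"])


# ---------------------------------------------------------------- functional

def _trait_distance(traits: pd.DataFrame) -> np.ndarray:
    """Pairwise trait distance: |difference| for one trait, Euclidean on
    z-scored traits for several."""
    X = traits.to_numpy(dtype=float)
    if X.shape[1] > 1:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return squareform(pdist(X, metric="euclidean"))


def functional_structure(
    peak_table: PeakTable,
    trait_table: pd.DataFrame,
    traits: Sequence[str],
    metric: str = "CWM",
) -> pd.DataFrame:
    """Community-weighted mean or Rao's quadratic entropy per sample.

    CWM_t = sum_i p_i t_i for each requested trait. RaoQ = sum_ij p_i p_j d_ij
    where d is the pairwise trait distance over the requested trait set.
    Molecules with missing trait values are excluded with renormalization.
    """
    cols = list(traits)
    tt = trait_table.reindex(peak_table.molecules)[cols]
    missing = tt.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} molecules with missing traits",
                      stacklevel=2)
        tt = tt[~missing]
    pt = peak_table.subset_molecules(tt.index)
    ra = pt.relative_abundance()

    if metric == "CWM":
        out = ra.T @ tt
        out.columns = [f"cwm_{c}" for c in cols]
        return out
    if metric == "RaoQ":
        D = _trait_distance(tt)
        P = ra.to_numpy()
        vals = np.einsum("is,ij,js->s", P, D, P)
        return pd.DataFrame({"raoq": vals}, index=ra.columns)
    raise ValueError(f"unknown metric {metric!r}")


def raoq_bruteforce(p: np.ndarray, d: np.ndarray) -> float:
    """Double-loop RaoQ; independent oracle for the vectorized path."""
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * d[i, j]
    return q


# ---------------------------------------------------------------- dendrograms

def _normalize01(d: np.ndarray) -> np.ndarray:
    lo, hi = d.min(), d.max()
    if hi == lo:
        raise ValueError("degenerate distance matrix: all pairwise distances equal")
    return (d - lo) / (hi - lo)


def transformation_hop_distance(network: TransformationNetwork,
                                ids: Sequence[str]) -> np.ndarray:
    """Shortest-path hop counts between molecules in the transformation
    network; disconnected pairs get (max finite hop distance + 1)."""
    idx = {m: k for k, m in enumerate(network.ids)}
    sub = [idx[m] for m in ids]
    A = nx.to_scipy_sparse_array(network.graph, nodelist=network.ids, format="csr")
    A.data = np.ones_like(A.data)
    D = shortest_path(A, method="D", unweighted=True, indices=sub)[:, sub]
    finite = np.isfinite(D)
    if not finite.all():
        offdiag = D[finite]
        cap = (offdiag.max() if offdiag.size else 0.0) + 1.0
        D = np.where(finite, D, cap)
    return D


def build_dendrogram(
    trait_table: pd.DataFrame | None = None,
    transformation_network: TransformationNetwork | None = None,
    kind: str = "MCD",
    traits: Sequence[str] | None = None,
) -> Dendrogram:
    """Average-linkage molecular dendrogram.

    MCD clusters Euclidean distances of z-scored traits; TD clusters
    shortest-path hop distances in the transformation network; TWCD
    clusters the element-wise product of the two min-max-normalized
    distance matrices.
    """
    if kind in ("MCD", "TWCD"):
        if trait_table is None:
            raise ValueError(f"{kind} requires a trait table")
        cols = list(traits) if traits is not None else list(trait_table.columns)
        tt = trait_table[cols].dropna()
        if len(tt) < 2:
            raise ValueError("need at least 2 molecules with complete traits")
        if (tt.std(ddof=0) == 0).all():
            raise ValueError("all trait rows identical; no structure to cluster")
        ids = list(tt.index)
        d_mcd = _trait_distance(tt)
    if kind in ("TD", "TWCD"):
        if transformation_network is None:
            raise ValueError(f"{kind} requires a transformation network")
        if kind == "TD":
            ids = list(transformation_network.ids)
            if len(ids) < 2:
                raise ValueError("need at least 2 molecules")
        d_td = transformation_hop_distance(transformation_network, ids)

    if kind == "MCD":
        d = d_mcd
    elif kind == "TD":
        d = d_td
    elif kind == "TWCD":
        d = _normalize01(d_mcd) * _normalize01(d_td)
    else:
        raise ValueError(f"unknown dendrogram kind {kind!r}")

    Z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=Z, ids=ids, kind=kind)


# ---------------------------------------------------------------- dendrogram diversity

def mpd_mntd(
    dist: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean pairwise and mean nearest-taxon distance for one assemblage.

    ``dist`` is the square cophenetic matrix restricted to present
    molecules; ``weights`` (relative abundances) switch on abundance
    weighting, otherwise every molecule counts equally.
    """
    n = dist.shape[0]
    if n < 2:
        return np.nan, np.nan
    off = ~np.eye(n, dtype=bool)
    nearest = np.where(off, dist, np.inf).min(axis=1)
    if weights is None:
        mpd = float(dist[off].mean())
        mntd = float(nearest.mean())
    else:
        w = weights / weights.sum()
        W = np.outer(w, w)[off]
        mpd = float((dist[off] * W).sum() / W.sum())
        mntd = float((nearest * w).sum())
    return mpd, mntd


def dendro_diversity(
    dendrogram: Dendrogram,
    peak_table: PeakTable,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-sample dendrogram diversity (Faith-style DD), MPD and MNTD.

    DD is the total branch length of the subtree spanned by the molecules
    present in the sample. MPD/MNTD are unweighted by default, matching the
    incidence-based stance of the null models downstream.
    """
    missing = peak_table.molecules.difference(dendrogram.ids)
    if len(missing):
        raise ValueError(f"{len(missing)} molecules absent from dendrogram tips")
    tree = dendrogram.to_tree()
    D = dendrogram.cophenetic_matrix()
    pos = {m: i for i, m in enumerate(D.index)}
    Dv = D.to_numpy()
    ra = peak_table.relative_abundance()
    rows = []
    for sample in peak_table.samples:
        p = ra[sample]
        present = p.index[p > 0]
        if len(present) == 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        counts = (p > 0).astype(int).reindex(dendrogram.ids).fillna(0).to_numpy()
        dd = float(faith_pd(counts, dendrogram.ids, tree))
        idx = [pos[m] for m in present]
        sub = Dv[np.ix_(idx, idx)]
        w = p[present].to_numpy() if weighted else None
        mpd, mntd = mpd_mntd(sub, w)
        rows.append((dd, mpd, mntd))
    return pd.DataFrame(rows, index=peak_table.samples, columns=["dd", "mpd", "mntd"])


# ---------------------------------------------------------------- dissimilarity

def dissimilarity(
    peak_table: PeakTable,
    metric: str = "bray_curtis",
    dendrogram: Dendrogram | None = None,
) -> pd.DataFrame:
    """Sample x sample dissimilarity matrix.

    Supported metrics: ``jaccard`` (incidence), ``bray_curtis`` (on relative
    abundances), ``unifrac_unweighted`` and ``unifrac_weighted`` (need a
    dendrogram covering every molecule).
    """
    samples = list(peak_table.samples)
    if metric == "jaccard":
        X = peak_table.presence().T.to_numpy().astype(bool)
        dm = squareform(pdist(X, metric="jaccard"))
    elif metric == "bray_curtis":
        X = peak_table.relative_abundance().T.to_numpy()
        dm = squareform(pdist(X, metric="braycurtis"))
    elif metric in ("unifrac_unweighted", "unifrac_weighted"):
        if dendrogram is None:
            raise ValueError(f"{metric} requires a dendrogram")
        missing = peak_table.molecules.difference(dendrogram.ids)
        if len(missing):
            raise ValueError(f"{len(missing)} molecules absent from dendrogram tips")
        counts = peak_table.relative_abundance().reindex(dendrogram.ids).fillna(0.0).T
        name = ("unweighted_unifrac" if metric == "unifrac_unweighted"
                else "weighted_unifrac")
        kwargs = {"normalized": True} if name == "weighted_unifrac" else {}
        dm = beta_diversity(name, counts.to_numpy(), ids=samples,
                            taxa=dendrogram.ids, tree=dendrogram.to_tree(),
                            **kwargs).data
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(dm, index=samples, columns=samples)


def pcoa(distance_matrix: pd.DataFrame, k: int | None = None):
    """Classical scaling (PCoA) of a square symmetric distance matrix.

    Returns ``(coordinates, eigenvalues)``; negative eigenvalues are
    reported, not dropped.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    ids = list(distance_matrix.index) if isinstance(distance_matrix, pd.DataFrame) \
        else [str(i) for i in range(d.shape[0])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(d, ids), method="eigh",
                          warn_neg_eigval=False)
    coords = res.samples
    eigvals = res.eigvals
    if k is not None:
        coords = coords.iloc[:, :k]
    coords.index = pd.Index(ids)
    return coords, eigvals
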