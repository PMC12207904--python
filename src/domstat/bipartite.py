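"""DOM-microbe bipartite networks and the H2' specialization index.

Signed SparCC correlations between molecules and microbial genera are
turned into integer-weighted bipartite webs (|rho| x 100,000, rounded),
separately for the negative (rho < -0.50, putative degradation) and
positive (rho > 0.50, putative production) strata. Specialization is the
two-dimensional Shannon entropy H2 of the interaction matrix,
standardized between its marginal-constrained extremes:

    H2' = (H2_max - H2) / (H2_max - H2_min)

and additionally standardized against shuffled-web null models (cell
values reassigned to random positions) as an SES.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PeakTable
from .darknet import sparcc


@dataclass
class BipartiteWeb:
    """Nonnegative integer molecules x genera interaction matrix."""

    weights: pd.DataFrame
    sign: str  # 'positive' | 'negative'

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("empty web (all weights zero)")

    @property
    def total(self) -> float:
        return float(self.weights.to_numpy().sum())

    def trimmed(self) -> "BipartiteWeb":
        """Drop all-zero rows and columns."""
        w = self.weights
        w = w.loc[w.sum(axis=1) > 0, w.sum(axis=0) > 0]
        return BipartiteWeb(w, self.sign)

    def subweb(self, molecules, genera) -> "BipartiteWeb":
        w = self.weights.loc[
            self.weights.index.intersection(molecules),
            self.weights.columns.intersection(genera),
        ]
        return BipartiteWeb(w, self.sign).trimmed()


def dom_microbe_correlations(
    molecules: PeakTable,
    genera: PeakTable,
    min_occupancy: float = 0.30,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Molecule x genus SparCC correlation block.

    Both tables are occupancy-filtered (present in more than 30% of
    samples by default), stacked and passed through the SparCC estimator
    once; the cross block is returned.
    """
    mol_f = molecules.filter_occupancy(min_occupancy, strict=True)
    gen_f = genera.filter_occupancy(min_occupancy, strict=True)
    stacked = pd.concat([mol_f.intensities, gen_f.intensities])
    corr = sparcc(stacked, **sparcc_kwargs)
    return corr.loc[mol_f.molecules, gen_f.molecules]


def build_bipartite(
    corr: pd.DataFrame,
    sign: str = "positive",
    rho_cut: float = 0.50,
    weight_scale: int = 100_000,
) -> BipartiteWeb:
    """Integer-weighted web from a molecule x genus correlation block.

    Positive mode keeps rho > rho_cut, negative mode rho < -rho_cut;
    weights are round(|rho| * weight_scale).
    """
    r = corr.to_numpy(dtype=float)
    if sign == "positive":
        mask = r > rho_cut
    elif sign == "negative":
        mask = r < -rho_cut
    else:
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    w = np.where(mask, np.round(np.abs(r) * weight_scale), 0.0).astype(np.int64)
    web = pd.DataFrame(w, index=corr.index, columns=corr.columns)
    web = web.loc[web.sum(axis=1) > 0, web.sum(axis=0) > 0]
    if web.size == 0 or web.to_numpy().sum() == 0:
        raise ValueError(f"empty {sign} web after |rho| > {rho_cut} filtering")
    return BipartiteWeb(web, sign)


# ---------------------------------------------------------------- entropy

def h2(web: BipartiteWeb | pd.DataFrame | np.ndarray) -> float:
    """Two-dimensional Shannon entropy (nats) of the interaction matrix."""
    w = _weights(web)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero web")
    p = w[w > 0] / total
    return float(-(p * np.log(p)).sum())


def _weights(web) -> np.ndarray:
    if isinstance(web, BipartiteWeb):
        return web.weights.to_numpy(dtype=float)
    return np.asarray(web, dtype=float)


def h2_bounds(web: BipartiteWeb | pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """(H2_min, H2_max) under the observed marginal totals.

    H2_max is the entropy of the independence table (outer product of
    marginal shares), the exact maximum under fixed marginals. H2_min is a
    greedy minimal-entropy allocation that repeatedly pairs the largest
    remaining row and column totals; since the observed web is itself a
    feasible allocation, the observed entropy caps the estimate, which
    guarantees H2_min <= H2 <= H2_max.
    """
    w = _weights(web)
    total = w.sum()
    r = w.sum(axis=1) / total
    c = w.sum(axis=0) / total
    r_pos = r[r > 0]
    c_pos = c[c > 0]
    h2_max = float(-(r_pos * np.log(r_pos)).sum() - (c_pos * np.log(c_pos)).sum())

    rr = r.copy()
    cc = c.copy()
    cells = []
    while rr.max() > 1e-15 and cc.max() > 1e-15:
        i = int(np.argmax(rr))
        j = int(np.argmax(cc))
        a = min(rr[i], cc[j])
        cells.append(a)
        rr[i] -= a
        cc[j] -= a
    cells = np.array(cells)
    cells = cells[cells > 0]
    greedy = float(-(cells * np.log(cells)).sum())
    h2_min = min(greedy, h2(w))
    return h2_min, h2_max


def h2_prime(web: BipartiteWeb | pd.DataFrame | np.ndarray) -> float:
    """Marginal-standardized specialization: 1 = maximally specialized
    (H2 at its marginal-constrained minimum), 0 = independence."""
    obs = h2(web)
    lo, hi = h2_bounds(web)
    if hi - lo <= 1e-12:
        warnings.warn("degenerate web: H2_max == H2_min; H2' defined as 0",
                      stacklevel=2)
        return 0.0
    return float((hi - obs) / (hi - lo))


# ---------------------------------------------------------------- null models

@dataclass
class SpecializationResult:
    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_null: int
    seed: int
    statistic: str


def shuffle_web(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign the observed nonzero cell values to uniformly chosen
    distinct positions of a same-shaped matrix (value multiset and
    dimensions preserved; marginals free)."""
    flat = w.ravel()
    values = flat[flat > 0]
    out = np.zeros_like(flat)
    pos = rng.choice(flat.size, size=values.size, replace=False)
    out[pos] = rng.permutation(values)
    return out.reshape(w.shape)


def ses_h2(
    web: BipartiteWeb,
    n_null: int = 999,
    statistic: str = "h2_prime",
    seed: int = 0,
) -> SpecializationResult:
    """Standardized effect size of specialization vs shuffled-web nulls.

    ``statistic`` selects what is standardized: ``h2_prime`` (default) or
    raw ``h2``. The two-sided empirical p-value uses the (r+1)/(n+1) rank
    rule. Deterministic for a fixed seed.
    """
    if statistic not in ("h2_prime", "h2"):
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = h2_prime if statistic == "h2_prime" else h2
    rng = np.random.default_rng(seed)
    w = web.weights.to_numpy(dtype=np.int64)
    observed = stat(w)
    nulls = np.empty(n_null)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(n_null):
            nulls[k] = stat(shuffle_web(w, rng))
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1))
    if sd < 1e-10 * max(1.0, abs(mu)):
        raise ValueError("null distribution has zero spread (the statistic is "
                         "invariant under the shuffle null for this web)")
    ses = (observed - mu) / sd
    n_ge = int((nulls >= observed).sum())
    n_le = int((nulls <= observed).sum())
    p = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n_null + 1))
    lo, hi = h2_bounds(w)
    return SpecializationResult(
        h2=h2(w), h2_min=lo, h2_max=hi, h2_prime=h2_prime(w),
        null_mean=mu, null_sd=sd, ses=float(ses), p_value=p,
        n_null=n_null, seed=seed, statistic=statistic,
    )
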