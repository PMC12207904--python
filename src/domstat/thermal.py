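"""Molecule- and composition-level thermal response indicators.

Each molecule's environmental response (MER) is the Spearman correlation
of its relative abundance with temperature, fitted on a "training" subset
of samples. The compositional indicator iCER for a held-out sample is the
intensity-weighted mean of the statistically significant MERs of the
molecules present in it:

    iCER = sum(MER_i * I_i) / sum(I_i)

The 80:20 sample partition (per region, spanning the temperature
gradient) keeps MER fitting and iCER evaluation statistically
independent; the whole protocol is repeated with fresh random partitions
and the per-molecule MERs and per-sample iCERs averaged over repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- splitting

def split_dataset(
    metadata: pd.DataFrame,
    ratio: float = 0.8,
    stratify: Sequence[str] = ("region",),
    stratify_temperature: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive (mer_set, icer_set) sample split.

    Within each stratum (region by default) the MER set receives
    ``round(ratio * n)`` samples. When replicates allow, held-out samples
    are spread round-robin across temperature levels so both sets span the
    gradient. Deterministic for a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1) — an empty split is useless")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mer: list[str] = []
    icer: list[str] = []
    strata = metadata.groupby(list(stratify), sort=True) if stratify else [(None, metadata)]
    for _, sub in strata:
        n = len(sub)
        if n < 5:
            raise ValueError("stratum too small to split (need >= 5 samples)")
        n_icer = n - int(round(ratio * n))
        n_icer = max(n_icer, 1)
        if stratify_temperature and "temperature" in sub.columns:
            # round-robin over shuffled temperature levels
            temps = list(sub["temperature"].unique())
            rng.shuffle(temps)
            by_temp = {t: list(rng.permutation(sub.index[sub["temperature"] == t]))
                       for t in temps}
            chosen: list[str] = []
            while len(chosen) < n_icer:
                for t in temps:
                    if by_temp[t] and len(chosen) < n_icer:
                        chosen.append(by_temp[t].pop())
        else:
            chosen = list(rng.choice(sub.index, size=n_icer, replace=False))
        icer.extend(chosen)
        mer.extend(s for s in sub.index if s not in set(chosen))
    return mer, icer


# ---------------------------------------------------------------- MER

@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Exact permutation null of Spearman rho for n untied observations."""
    base = np.arange(n, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rhos = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return np.sort(np.abs(rhos))


def _spearman_vectorized(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each row of X against y.

    Large-sample t approximation for n >= 10, exact permutation null below
    (small per-stratum sample counts make the t approximation shaky there).
    """
    n = y.size
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (ry_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rx_c @ ry_c) / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    if n >= 10:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    else:
        null = _exact_spearman_null(n)
        # P(|rho_null| >= |rho_obs|), midpoint-free conservative count
        k = null.size - np.searchsorted(null, np.abs(rho) - 1e-12, side="left")
        p = k / null.size
    return rho, p


def compute_mer(
    peak_table: PeakTable,
    temperature: pd.Series,
    min_occupancy: float = 0.30,
) -> pd.DataFrame:
    """Per-molecule MER (Spearman rho of relative abundance vs temperature).

    Molecules detected in fewer than ``min_occupancy`` of the supplied
    samples are dropped (the filter guards against false correlations from
    low-occurrence molecules); constant-abundance molecules are dropped
    with a log entry. Returns columns ``mer``, ``p``, ``occupancy``.
    """
    temps = temperature.loc[peak_table.samples].to_numpy(dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("temperature must vary across samples")
    occ = peak_table.occupancy()
    kept = occ.index[occ >= min_occupancy]
    ra = peak_table.relative_abundance().loc[kept]
    X = ra.to_numpy()
    constant = X.std(axis=1) == 0
    if constant.any():
        logger.info("dropping %d constant-abundance molecules", int(constant.sum()))
    X = X[~constant]
    ids = kept[~constant]
    rho, p = _spearman_vectorized(X, temps)
    return pd.DataFrame({"mer": rho, "p": p, "occupancy": occ[ids]},
                        index=pd.Index(ids, name="id"))


def compute_icer(
    peak_table: PeakTable,
    mer: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.Series:
    """Per-sample iCER: relative-intensity-weighted mean of significant MERs.

    Weights are the focal sample's relative intensities of the contributing
    molecules, renormalized over contributors. Samples without any
    significant-MER molecule get NaN with a warning.
    """
    sig = mer.index[(mer["p"] < p_threshold) & mer["mer"].notna()]
    ra = peak_table.relative_abundance()
    out = {}
    contributors = sig.intersection(ra.index)
    mer_vals = mer.loc[contributors, "mer"]
    for sample in ra.columns:
        w = ra.loc[contributors, sample]
        total = w.sum()
        if total <= 0:
            warnings.warn(f"sample {sample!r}: no significant-MER molecules present",
                          stacklevel=2)
            out[sample] = np.nan
        else:
            out[sample] = float((mer_vals * w).sum() / total)
    return pd.Series(out, name="icer")


# ---------------------------------------------------------------- protocol

@dataclass
class ThermalResponse:
    """Aggregated MER/iCER output of the repeated-partition protocol."""

    mer_mean: pd.DataFrame      # per molecule: mean mer, n_repeats contributing
    icer_mean: pd.DataFrame     # per sample: mean icer, n_repeats in the held-out set
    n_repeats: int
    seed: int


def run_icer_protocol(
    peak_table: PeakTable,
    metadata: pd.DataFrame,
    n_repeats: int = 999,
    ratio: float = 0.8,
    min_occupancy: float = 0.30,
    p_threshold: float = 0.05,
    seed: int = 0,
    by_region: bool = True,
) -> ThermalResponse:
    """Repeated 80:20 partition protocol, per region.

    Each repeat draws a fresh stratified split from a sub-seed of the master
    seed, fits MERs on the MER set (occupancy filter applied within the
    region's MER set) and evaluates iCER on the held-out samples. Outputs
    per-molecule mean MER and per-sample mean iCER over the repeats in
    which they participated. No sample ever contributes to both the MER
    fit and its own iCER within a repeat.
    """
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=n_repeats)

    regions = metadata["region"].unique() if by_region else ["all"]
    mer_sums: dict[str, pd.Series] = {}
    mer_counts: dict[str, pd.Series] = {}
    icer_sum = pd.Series(0.0, index=peak_table.samples)
    icer_cnt = pd.Series(0, index=peak_table.samples)

    for rep in range(n_repeats):
        rng = np.random.default_rng(sub_seeds[rep])
        for region in regions:
            meta_r = metadata[metadata["region"] == region] if by_region else metadata
            pt_r = peak_table.subset_samples(meta_r.index)
            mer_samples, icer_samples = split_dataset(
                meta_r, ratio=ratio, stratify=(), stratify_temperature=True, seed=rng
            )
            assert not set(mer_samples) & set(icer_samples)
            mer_df = compute_mer(pt_r.subset_samples(mer_samples),
                                 meta_r["temperature"], min_occupancy=min_occupancy)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                icer = compute_icer(pt_r.subset_samples(icer_samples), mer_df,
                                    p_threshold=p_threshold)
            key = region
            if key not in mer_sums:
                mer_sums[key] = pd.Series(0.0, index=peak_table.molecules)
                mer_counts[key] = pd.Series(0, index=peak_table.molecules)
            mer_sums[key] = mer_sums[key].add(mer_df["mer"], fill_value=0.0)
            mer_counts[key] = mer_counts[key].add(
                pd.Series(1, index=mer_df.index), fill_value=0)
            ok = icer.dropna()
            icer_sum.loc[ok.index] += ok
            icer_cnt.loc[ok.index] += 1

    mer_frames = []
    for region in mer_sums:
        cnt = mer_counts[region].replace(0, np.nan)
        mer_frames.append(pd.DataFrame({
            "region": region,
            "mer_mean": mer_sums[region] / cnt,
            "n_repeats": mer_counts[region],
        }))
    mer_mean = pd.concat(mer_frames)
    icer_mean = pd.DataFrame({
        "icer_mean": icer_sum / icer_cnt.replace(0, np.nan),
        "n_repeats": icer_cnt,
    })
    return ThermalResponse(mer_mean=mer_mean, icer_mean=icer_mean,
                           n_repeats=n_repeats, seed=seed)


def icer_temperature_regression(
    response: ThermalResponse, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Linear fit of mean iCER against temperature per region."""
    rows = []
    for region, meta_r in metadata.groupby("region"):
        y = response.icer_mean.loc[meta_r.index, "icer_mean"].dropna()
        x = meta_r.loc[y.index, "temperature"]
        if len(y) < 3:
            rows.append((region, np.nan, np.nan, np.nan, len(y)))
            continue
        fit = stats.linregress(x, y)
        rows.append((region, fit.slope, fit.rvalue ** 2, fit.pvalue, len(y)))
    return pd.DataFrame(rows, columns=["region", "slope", "r2", "p", "n"]).set_index("region")
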