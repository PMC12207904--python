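"""Seeded generator of study-shaped DOM datasets with planted structure.

The generator emulates a warming-microcosm design — two regions
(subtropical, temperate), six incubation temperatures (5-30 degC) with
three replicates each, 36 samples in total — and produces the five input
tables the pipeline consumes: peak intensities, element compositions,
sample metadata, dark-matter intensities and genus abundances. Planted
warm-accumulating/-depleting molecules, molecule-molecule correlation
blocks and molecule-genus links give every downstream stage a known
ground truth.

Intensities follow a log-normal model with multiplicative temperature
effects: FT-ICR peak intensities are positive, right-skewed and only
meaningful relative to each other, which is exactly what the downstream
compositional methods assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classification import vk_class
from .containers import PeakTable
from .formula_core import MONOISOTOPIC

REGIONS = ("subtropical", "temperate")
TEMPERATURES = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class StudyDesign:
    """Factorial warming design: regions x temperature levels x replicates."""

    regions: tuple[str, ...] = REGIONS
    temperatures: tuple[int, ...] = TEMPERATURES
    replicates: int = 3

    @property
    def n_samples(self) -> int:
        return len(self.regions) * len(self.temperatures) * self.replicates

    def metadata(self) -> pd.DataFrame:
        rows = []
        for region in self.regions:
            for temp in self.temperatures:
                for rep in range(1, self.replicates + 1):
                    sid = f"{region[:3]}_T{temp:02d}_r{rep}"
                    rows.append((sid, region, temp, rep))
        meta = pd.DataFrame(rows, columns=["sample", "region", "temperature", "replicate"])
        return meta.set_index("sample")


@dataclass
class EffectConfig:
    """Planted effect sizes and noise levels of the intensity model.

    ``trend_slope`` is the per-degree-Celsius slope of log intensity for
    responder molecules; with ``noise_sigma`` 0.5 and the 5-30 degC
    gradient the default 0.08 yields Spearman-detectable responses
    (|rho| around 0.8) like strong responders in warming experiments.
    """

    frac_accumulating: float = 0.15
    frac_depleting: float = 0.15
    trend_slope: float = 0.08          # ln-intensity per degC for responders
    noise_sigma: float = 0.5           # ln-intensity residual sd
    baseline_mu: float = 13.8          # ln of a typical FT-ICR peak intensity
    baseline_sigma: float = 1.0
    rare_fraction: float = 0.3         # share of molecules thinned below 30% occupancy
    n_corr_blocks: int = 3
    corr_block_size: int = 10
    corr_block_loading: float = 0.8


@dataclass
class GroundTruth:
    """Everything that was planted, for parameter-recovery tests."""

    responders: dict = field(default_factory=dict)   # region -> {'accumulating': [...], 'depleting': [...]}
    rare_molecules: list = field(default_factory=list)
    corr_blocks: list = field(default_factory=list)  # list of id lists
    genus_links: list = field(default_factory=list)  # (molecule, genus, sign)
    dark_coupling: str = "independent"
    seeds: dict = field(default_factory=dict)


def generate_formulas(
    n: int = 1000,
    seed: int = 0,
    c_range: tuple[int, int] = (4, 50),
    hc_range: tuple[float, float] = (0.2, 2.3),
    oc_range: tuple[float, float] = (0.0, 1.2),
    max_tries: int = 50,
    min_vk_classes: int = 5,
) -> pd.DataFrame:
    """Random valid element compositions with computed monoisotopic masses.

    Constraints: C in ``c_range``, H/C and O/C in the van Krevelen ranges,
    N <= 3, S <= 2, P <= 1, and (H + N + P) even so the double-bond
    equivalent is an integer (even-electron molecules). The generated set
    must populate at least ``min_vk_classes`` van Krevelen classes, else
    the constraints are declared unsatisfiable; narrow deliberate
    constraints (e.g. labile-only H/C ranges) should lower the requirement.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    rows: dict[tuple, None] = {}
    for _ in range(max_tries):
        m = 2 * n
        c = rng.integers(c_range[0], c_range[1] + 1, size=m)
        h = np.round(rng.uniform(*hc_range, size=m) * c).astype(int)
        h = np.maximum(h, 1)
        o = np.round(rng.uniform(*oc_range, size=m) * c).astype(int)
        nn = rng.choice([0, 1, 2, 3], size=m, p=[0.55, 0.25, 0.15, 0.05])
        s = rng.choice([0, 1, 2], size=m, p=[0.8, 0.15, 0.05])
        p = rng.choice([0, 1], size=m, p=[0.9, 0.1])
        odd = (h + nn + p) % 2 == 1
        h = h + odd  # parity fix keeps DBE integral
        ok = h <= np.ceil(hc_range[1] * c).astype(int) + 1
        for tup in zip(c[ok], h[ok], o[ok], nn[ok], s[ok], p[ok]):
            rows.setdefault(tup, None)
            if len(rows) >= n:
                break
        if len(rows) >= n:
            break
    if len(rows) < n:
        raise ValueError("constraints unsatisfiable: could not generate enough "
                         "unique formulas")
    recs = list(rows)[:n]
    table = pd.DataFrame(recs, columns=["C", "H", "O", "N", "S", "P"])
    table["mass"] = (
        table["C"] * MONOISOTOPIC["C"] + table["H"] * MONOISOTOPIC["H"]
        + table["O"] * MONOISOTOPIC["O"] + table["N"] * MONOISOTOPIC["N"]
        + table["S"] * MONOISOTOPIC["S"] + table["P"] * MONOISOTOPIC["P"]
    )
    table.insert(0, "id", [f"mol{i:05d}" for i in range(n)])
    classes = {vk_class(o / c, h / c)
               for c, h, o in zip(table["C"], table["H"], table["O"])}
    if len(classes - {"others"}) < min_vk_classes:
        raise ValueError(f"constraints unsatisfiable: fewer than {min_vk_classes} "
                         "van Krevelen classes populated")
    return table[["id", "C", "H", "N", "O", "S", "P", "mass"]]


def _intensity_matrix(
    ids: list[str],
    meta: pd.DataFrame,
    effects: EffectConfig,
    rng: np.random.Generator,
    responders: dict,
    blocks: list[list[str]],
    block_factors: np.ndarray | None,
) -> pd.DataFrame:
    n_mol, n_smp = len(ids), len(meta)
    t_mid = np.mean(meta["temperature"].unique())
    log_i = rng.normal(effects.baseline_mu, effects.baseline_sigma,
                       size=(n_mol, 1)) + rng.normal(0, effects.noise_sigma,
                                                     size=(n_mol, n_smp))
    pos = {m: i for i, m in enumerate(ids)}
    temps = meta["temperature"].to_numpy(dtype=float)
    for region, sets in responders.items():
        in_region = (meta["region"] == region).to_numpy()
        dt = (temps - t_mid) * in_region
        for name, sign in (("accumulating", 1.0), ("depleting", -1.0)):
            idx = [pos[m] for m in sets.get(name, [])]
            log_i[idx, :] += sign * effects.trend_slope * dt[None, :]
    if block_factors is not None:
        for b, members in enumerate(blocks):
            idx = [pos[m] for m in members]
            log_i[idx, :] += effects.corr_block_loading * block_factors[b][None, :]
    return pd.DataFrame(np.exp(log_i), index=ids, columns=meta.index)


def generate_peak_table(
    design: StudyDesign,
    formulas: pd.DataFrame,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> tuple[PeakTable, GroundTruth]:
    """Peak intensities with planted thermal responders, correlation blocks
    and occupancy thinning; returns the table plus its ground truth."""
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    meta = design.metadata()
    ids = list(formulas["id"])
    n = len(ids)

    truth = GroundTruth(seeds={"peak_table": seed})
    shuffled = list(rng.permutation(ids))
    cursor = 0
    for region in design.regions:
        n_acc = int(round(effects.frac_accumulating * n))
        n_dep = int(round(effects.frac_depleting * n))
        acc = shuffled[cursor:cursor + n_acc]; cursor += n_acc
        dep = shuffled[cursor:cursor + n_dep]; cursor += n_dep
        truth.responders[region] = {"accumulating": acc, "depleting": dep}

    blocks = []
    for b in range(effects.n_corr_blocks):
        members = shuffled[cursor:cursor + effects.corr_block_size]
        cursor += effects.corr_block_size
        if len(members) == effects.corr_block_size:
            blocks.append(members)
    truth.corr_blocks = blocks
    factors = rng.normal(size=(len(blocks), len(meta))) if blocks else None

    intensities = _intensity_matrix(ids, meta, effects, rng,
                                    truth.responders, blocks, factors)

    n_rare = int(round(effects.rare_fraction * n))
    rare = list(rng.choice(ids, size=n_rare, replace=False))
    truth.rare_molecules = rare
    detect_p = rng.uniform(0.05, 0.25, size=n_rare)
    for m, q in zip(rare, detect_p):
        keep = rng.random(len(meta)) < q
        intensities.loc[m, ~keep] = 0.0
    # ensure no empty samples
    if (intensities.sum(axis=0) <= 0).any():
        raise RuntimeError("generator produced an empty sample; lower rare_fraction")
    return PeakTable(intensities), truth


def generate_dark_and_microbes(
    design: StudyDesign,
    peak_table: PeakTable,
    truth: GroundTruth,
    coupling: str = "independent",
    n_dark: int = 1000,
    n_genera: int = 100,
    n_genus_links: int = 10,
    effects: EffectConfig | None = None,
    seed: int = 1,
) -> tuple[PeakTable, pd.Series, PeakTable]:
    """Dark-matter peaks and genus abundances coupled to the known table.

    ``coupling`` controls the dark pool: ``independent`` dark peaks carry
    no shared structure (network connectivity drops when they replace
    known nodes), ``mirrored`` dark peaks statistically replicate known
    molecules (near-zero dark-matter effect), ``planted-links`` behaves
    like independent but additionally plants signed molecule-genus
    co-trends recoverable by correlation networks.

    Returns (dark peak table, dark masses, genus table); planted links are
    appended to ``truth``.
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    meta = design.metadata()
    if coupling not in ("independent", "mirrored", "planted-links"):
        raise ValueError(f"unknown coupling {coupling!r}")
    truth.dark_coupling = coupling
    truth.seeds["dark_microbes"] = seed
    dark_ids = [f"dark{i:05d}" for i in range(n_dark)]
    dark_masses = pd.Series(
        np.sort(rng.uniform(100.0, 800.0, size=n_dark)), index=dark_ids, name="mass"
    )

    if coupling == "mirrored":
        # sample sources without replacement when possible: duplicated
        # sources would plant near-perfect dark-dark correlations that the
        # known pool lacks, biasing exchangeability comparisons
        replace = n_dark > len(peak_table.molecules)
        src = rng.choice(len(peak_table.molecules), size=n_dark, replace=replace)
        base = peak_table.intensities.to_numpy()[src, :]
        noise = np.exp(rng.normal(0, 0.1, size=base.shape))
        dark = pd.DataFrame(np.where(base > 0, base * noise, 0.0),
                            index=dark_ids, columns=peak_table.samples)
    else:
        log_i = rng.normal(effects.baseline_mu, effects.baseline_sigma,
                           size=(n_dark, 1)) + rng.normal(
            0, effects.noise_sigma, size=(n_dark, len(meta)))
        dark = pd.DataFrame(np.exp(log_i), index=dark_ids, columns=meta.index)

    genus_ids = [f"genus{i:03d}" for i in range(n_genera)]
    log_g = rng.normal(0.0, 1.0, size=(n_genera, 1)) + rng.normal(
        0, effects.noise_sigma, size=(n_genera, len(meta)))
    t_mid = np.mean(meta["temperature"].unique())
    dt = (meta["temperature"].to_numpy(dtype=float) - t_mid)

    if coupling == "planted-links":
        mols = list(rng.choice(peak_table.molecules, size=n_genus_links, replace=False))
        gens = list(rng.choice(genus_ids, size=n_genus_links, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_genus_links)
        gpos = {g: i for i, g in enumerate(genus_ids)}
        for mol, gen, sign in zip(mols, gens, signs):
            # shared latent trend: molecule and genus co-vary along temperature
            factor = effects.trend_slope * dt
            gi = gpos[gen]
            log_g[gi, :] += sign * factor * 2.0
            peak_table.intensities.loc[mol] = (
                peak_table.intensities.loc[mol].to_numpy()
                * np.exp(factor * 2.0)
            )
            truth.genus_links.append((mol, gen, int(sign)))

    genus = np.exp(log_g)
    genus = genus / genus.sum(axis=0, keepdims=True)  # compositional closure
    genus_table = PeakTable(pd.DataFrame(genus, index=genus_ids, columns=meta.index))
    return PeakTable(dark), dark_masses, genus_table


def generate_study(
    seed: int = 0,
    n_molecules: int = 1000,
    n_dark: int = 1000,
    n_genera: int = 100,
    design: StudyDesign | None = None,
    effects: EffectConfig | None = None,
    coupling: str = "independent",
):
    """One-call generator: formulas, peaks, metadata, dark matter, microbes.

    Returns a dict with keys ``design``, ``metadata``, ``formulas``,
    ``peaks``, ``dark``, ``dark_masses``, ``genera``, ``truth``. All
    randomness derives from the master seed.
    """
    design = design or StudyDesign()
    master = np.random.default_rng(seed)
    s_formulas, s_peaks, s_dark = master.integers(0, 2**31 - 1, size=3)
    formulas = generate_formulas(n_molecules, seed=int(s_formulas))
    peaks, truth = generate_peak_table(design, formulas, effects=effects,
                                       seed=int(s_peaks))
    dark, dark_masses, genera = generate_dark_and_microbes(
        design, peaks, truth, coupling=coupling, n_dark=n_dark,
        n_genera=n_genera, effects=effects, seed=int(s_dark))
    truth.seeds["master"] = seed
    return {
        "design": design,
        "metadata": design.metadata(),
        "formulas": formulas,
        "peaks": peaks,
        "dark": dark,
        "dark_masses": dark_masses,
        "genera": genera,
        "truth": truth,
    }
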