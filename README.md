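# domstat

Statistical analysis of dissolved organic matter (DOM) molecular data from
high-resolution mass spectrometry (FT-ICR MS), for biogeochemists and
microbial ecologists who want to move from peak lists to ecological
inference.

FT-ICR MS resolves a DOM sample into thousands of exact-mass peaks, most of
which can be assigned a molecular formula (C, H, N, O, S, P). `domstat`
treats those molecules as *species* and each sample's relative peak
intensities as *abundances*, so the machinery of community ecology applies:

* **Molecular traits and classes** — for each formula: O/C, H/C, N/C, P/C,
  S/C, double-bond equivalents DBE = 1 + (2C − H + N + P)/2 and its variants
  DBE−O and DBE−AI, the modified aromaticity index
  AI_mod = (1 + C − ½O − S − ½(N + P + H)) / (C − ½O − N − S − P) clamped to
  [0, 1], nominal oxidation state of carbon
  NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C, the affine Gibbs free energy
  estimate GFE = 60.3 − 28.5·NOSC (kJ (mol C)⁻¹), and the CH2-series
  Kendrick mass defect. Molecules are classified into element-composition
  groups (CHO … CHONSP), van Krevelen biomolecular classes (lipids,
  proteins, amino sugars, carbohydrates, UnsatHC, lignin, tannin, ConHC),
  and reactivity–activity fractions (LA/LI/RA/RI) that combine the H/C
  lability cutoff of 1.5 with the molecule's count of putative biochemical
  transformations (mass-difference matches against a moiety database).
* **Chemodiversity** — richness, Shannon, Gini–Simpson, Pielou; CWM and
  Rao's quadratic entropy on traits; molecular dendrograms (MCD from
  traits, TD from the transformation network, TWCD combining both) with
  Faith-style dendrogram diversity, MPD and MNTD; Jaccard, Bray–Curtis and
  UniFrac dissimilarity with PCoA ordination.
* **Assembly null models** — βMNTD between sample pairs on a molecular
  dendrogram, standardized against tip-label-permutation nulls:
  βNTI = (βMNTD_obs − mean βMNTD_null) / sd(βMNTD_null). βNTI > 2 flags
  variable selection, βNTI < −2 homogeneous selection, |βNTI| ≤ 2
  stochastic assembly; runs on whole DOM or per reactivity–activity
  fraction.
* **Thermal response** — per-molecule environmental response
  MER_i = Spearman ρ(relative abundance, temperature), fitted on an 80%
  sample partition, aggregated on the held-out 20% as
  iCER = Σ(MER_i · I_i) / Σ(I_i) over molecules with significant MERs
  (p < 0.05, ≥30% occupancy), with the partition redrawn 999 times.
* **Dark-matter effects** — SparCC compositionality-robust correlation
  networks over known and unassigned ("dark") peaks; the indicator
  iDME (%) = (mean M_DK / mean M_KK − 1)·100 compares mean degree between
  known-only (KK) and half-dark (DK) 400-node networks over 100 random
  node draws, and decomposes exactly into dark–dark (intra), dark–known
  (inter) and known-link-change parts.
* **DOM–microbe specialization** — bipartite webs from signed SparCC
  correlations (|ρ| > 0.50), integer weights round(|ρ|·100 000), the
  two-dimensional Shannon entropy H2 and its marginal-standardized index
  H2′ = (H2max − H2)/(H2max − H2min), plus SES against shuffled-web nulls.

A seeded synthetic-data generator reproduces the shape of a warming
microcosm study (2 regions × 6 temperatures × 3 replicates = 36 samples)
with planted thermal responders, correlation blocks and molecule–genus
links, so every stage has a ground truth to recover.

## Worked example

```python
from domstat import compute_traits, idme
from domstat.formula_core import formulas_from_table
from domstat.synthetic import generate_study
from domstat.thermal import run_icer_protocol, icer_temperature_regression

study = generate_study(seed=1, n_molecules=400, n_dark=400, n_genera=50)
traits = compute_traits(formulas_from_table(study["formulas"]))
print(traits[["o_c", "h_c", "ai_mod", "nosc", "gfe"]].head(3).round(3))

response = run_icer_protocol(study["peaks"], study["metadata"],
                             n_repeats=99, seed=1)
print(icer_temperature_regression(response, study["metadata"]).round(3))

effect = idme(study["peaks"], study["dark"], n_nodes=200,
              n_replicates=20, seed=1)
print(f"iDME = {effect.idme:+.1f}%")
```

prints

```
            o_c    h_c  ai_mod   nosc     gfe
id
mol00000  0.000  0.875   0.600 -0.750  81.675
mol00001  0.074  0.296   0.885 -0.148  64.522
mol00002  0.304  1.478   0.143 -0.609  77.648
             slope     r2    p   n
region
subtropical  0.049  0.970  0.0  18
temperate    0.049  0.953  0.0  18
iDME = -46.7%
```

The first block is the per-molecule trait table. The second shows that the
mean iCER of each sample rises linearly with incubation temperature in both
regions (positive slope, R² ≈ 0.95) — the generator planted warm-responding
molecules and the repeated-partition protocol recovers them. The negative
iDME says that replacing half of the known molecules with (here,
structure-free) dark-matter peaks removes about half of the network's mean
degree: independent dark matter dilutes connectivity.

The same analyses are available from the shell:

```
domstat simulate --seed 1 --out sim/
domstat traits --formulas sim/formulas.tsv --out out/
domstat icer --peaks sim/peaks.tsv --metadata sim/metadata.tsv --out out/
domstat idme --peaks sim/peaks.tsv --dark sim/dark.tsv --out out/
```

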