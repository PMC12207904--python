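# Methods

This note documents the models behind `domstat`, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions taken where the underlying
methods leave room.

## Molecules as species

All analyses rest on one analogy: an FT-ICR MS peak list is a community
sample in which each resolved molecule is a species and its relative peak
intensity its abundance. The analogy is imperfect — peak intensity is an
ionization-weighted proxy, not a concentration — and the package therefore
defaults to *incidence-based* (presence/absence) weighting wherever a null
model is involved (βNTI, fraction-level assembly), with abundance
weighting available by flag. Relative abundances are per-sample closures
p_ij = I_ij / Σ_i I_ij; all downstream statistics use either these shares
or presence.

## Traits

Traits are pure functions of the element counts (C, H, N, O, S, P) and
the neutral monoisotopic mass:

* DBE = 1 + (2C − H + N + P)/2; DBE_O = DBE − O;
  DBE_AI = 1 + C − O − S − 0.5(H + N + P).
* AI_mod = (1 + C − 0.5·O − S − 0.5·(N + P + H)) / (C − 0.5·O − N − S − P),
  set to 0 when the denominator is ≤ 0 or the ratio negative, and capped
  at 1. The clamp avoids spurious negative or unbounded aromaticity for
  H-rich or heteroatom-rich formulas.
* NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C and GFE = 60.3 − 28.5·NOSC in
  kJ (mol C)⁻¹. GFE is affine in NOSC by construction; the test suite
  asserts the identity exactly.
* Kendrick mass KM = mass · 14 / m(CH2) with m(CH2) the *exact*
  monoisotopic CH2 mass (14.015650064 Da), and defect = round(KM) − KM.
  Using the exact divisor (rather than the five-decimal 14.01565
  convention) keeps the defect constant along CH2 homologous series to
  float precision, which is the property the trait exists for; a
  floor-based nominal-mass dialect is available by argument.
* Y_met (carbon use efficiency) is exposed as a pluggable hook
  (`compute_traits(..., y_met=...)`) with no default implementation: no
  single published closed form is canonical, so the column is only
  produced when the caller supplies a definition.

Ion-mode handling: inputs are assumed neutral; a flag converts [M−H]⁻ ion
masses by adding one proton mass. When both counts and a measured mass are
given they are cross-checked at 5 mDa by default.

## Transformations

Two molecules are linked by a putative biochemical transformation when
their exact-mass difference matches a database entry within ±0.001 Da
(FT-ICR accuracy is well below 1 mDa; a ppm-relative tolerance is
available). The packaged database lists ~80 moieties — condensation and
elimination units, proteinogenic amino-acid residues, glycan residues —
as composition strings whose mass differences are computed from atomic
masses at load time, so they are exact by construction. The matcher sorts
masses once and slides a window per database entry; a naive O(n²) double
loop ships alongside it as the test oracle, and the two are asserted
edge-identical. A molecule's transformation count is its degree in this
network.

## Classification

* Element groups concatenate the present heteroatoms onto "CHO" in fixed
  N, S, P order; oxygen-free formulas get a "non-CHO" label.
* Van Krevelen classes use the standard rectangular regions in the
  (O/C, H/C) plane. The region list is matched first-to-last with
  lower-inclusive/upper-exclusive bounds, which makes labels
  deterministic on shared box edges (e.g. lignin vs ConHC at H/C = 0.7).
* Reactivity–activity fractions: labile means H/C ≥ 1.5; active means
  more than 10 transformations, inactive at most 1; anything between
  falls into "others". Both cutoffs are configurable but default to the
  published convention.
* Class compositions are share sums per sample; unlabelled molecules stay
  in the denominator under "others" by default (configurable), so rows
  always sum to 1.

## Diversity and dendrograms

Taxonomic indices are the textbook forms (Shannon in nats, Gini–Simpson,
Pielou = H/ln S, undefined for S = 1). CWM is the abundance-weighted trait
mean; RaoQ is the full double sum Σ p_i p_j d_ij with d = |Δt| for one
trait and Euclidean distance on z-scored traits for several. Traits are
z-scored before any multi-trait distance because their units are
incommensurate (Da vs ratios vs kJ).

Dendrograms are average-linkage trees: MCD on z-scored trait distances,
TD on shortest-path hop counts in the transformation network
(disconnected pairs are set to the largest finite hop distance + 1, which
keeps the matrix finite while preserving order), and TWCD on the
element-wise product of the two min–max-normalized distance matrices.
The TWCD combination is an interpretation — the source methods do not
print a formula — and is flagged as such; both ingredient matrices are
normalized to [0, 1] first so neither dominates. Dendrogram diversity
(DD) is Faith-style total branch length (via scikit-bio's `faith_pd` on
the linkage-derived tree), MPD/MNTD are computed on the cophenetic
matrix, unweighted by default. Dissimilarity wraps scipy/scikit-bio
implementations (Jaccard on presence, Bray–Curtis on shares, both UniFrac
flavours on the dendrogram); PCoA is classical scaling with negative
eigenvalues reported, never dropped.

## Assembly (βMNTD/βNTI)

βMNTD between samples A and B is
0.5·[Σ_{i∈A} w_i min_{j∈B} d_ij + Σ_{j∈B} w_j min_{i∈A} d_ij] on the
cophenetic matrix, with w = 1/S (incidence, default) or relative
abundance. The null randomizes dendrogram associations by permuting tip
labels — the standard taxa-label null of the phylogenetic literature the
index comes from. One permutation per iteration is shared across all
sample pairs (the nulls stay exchangeable per pair and the run is ~pairs
times faster); per-pair permutations are available by flag. n_null
defaults to 999 with a hard floor of 99; a zero-spread null raises a
descriptive error rather than dividing by zero. βNTI > 2 → variable
selection, < −2 → homogeneous selection, ties at exactly ±2 → stochastic
(the published thresholds are strict inequalities on both sides, leaving
the boundary open; assigning it to stochastic is conservative).
Fraction-level assembly restricts tips and samples to one
reactivity–activity fraction at a time, runs incidence-based βNTI within
sample groups (e.g. regions), and skips pairs with fewer than two
fraction molecules on either side, logging each skip.

Calibration: for exchangeable random assemblages the test suite requires
the empirical P(|βNTI| > 2) to stay within a wide binomial band around
the nominal 0.05 (≤ 0.13 at 100 pairs, ~99.9% coverage); assemblages
drawn from disjoint clades must be flagged βNTI > 2 in ≥ 90% of pairs.

## Thermal response (MER/iCER)

Per repeat, samples are split 80:20 within each region; the held-out
samples are chosen round-robin across temperature levels so both subsets
span the gradient. The MER-set occupancy filter (≥ 30%) is evaluated
within the focal region's MER samples, because the filter exists to
protect the MER fit from low-occurrence molecules. MERs are Spearman ρ
of relative abundance against temperature with two-sided p-values from
the large-sample t approximation for n ≥ 10 and an exact permutation
null below that (small strata make the approximation shaky; the exact
null assumes untied data and is approximate in the presence of tied
temperatures). iCER for a held-out sample is the weighted mean of the
significant MERs (p < 0.05) with weights the sample's relative
intensities of the contributing molecules, renormalized over those
contributors — so iCER is a convex combination of MERs by construction.
The protocol repeats 999 times by default (sub-seeds drawn from the
master seed), averaging MERs per molecule and iCERs per sample over the
repeats in which they participated; the iCER–temperature regression is
fitted once on those means. No sample ever informs both the MER fit and
its own iCER within a repeat; the code asserts the disjointness
structurally.

## Dark-matter networks (SparCC/iDME)

Correlations are estimated with the SparCC log-ratio-variance estimator:
T_ij = var(log x_i/x_j), basis variances from the linear system under the
sparsity assumption, ρ_ij = (ω_i² + ω_j² − T_ij)/(2ω_iω_j), with up to 20
rounds of excluding the single most strongly correlated pair (|ρ| > 0.7)
from the system. Zeros are replaced by half the smallest positive
relative abundance before taking logs. There is no Dirichlet resampling
stage: FT-ICR intensities are not counts, so count-resampling noise has
no analogue; the estimator is deterministic given the data. Pearson
correlation on clr-transformed data ships alongside as an independent
sign cross-check.

iDME estimates correlations once, globally, on the pooled known + dark
molecules present in more than 30% of samples; each of the (default 100)
replicates draws a KK node set from the known pool and a DK set that
replaces half (or the observed dark:known share) of those nodes with dark
peaks, then measures mean degree 2E/N of the |ρ| ≥ 0.30 thresholded
induced subgraph. iDME is the ratio of replicate means
(mean M_DK / mean M_KK − 1)·100, matching the bars in the defining
equation, and the partition classifies every DK edge by endpoint kind:
intra = 100·mean(M_dd)/mean(M_KK), inter = 100·mean(M_dk)/mean(M_KK),
known-link change = 100·(mean(M_kk-links) − mean(M_KK))/mean(M_KK). The
three parts sum to iDME exactly because degree is additive over edge
classes; the source literature does not print a partition formula, and
this endpoint-class decomposition was chosen because it is exact and
testable. A degenerate KK network (zero mean degree) raises rather than
dividing by zero.

## Bipartite specialization (H2/H2′)

Molecule–genus webs come from one global SparCC run over the stacked,
occupancy-filtered molecule and genus tables; the cross block is
thresholded at ρ > 0.50 (positive webs) or ρ < −0.50 (negative webs) and
integerized as round(|ρ|·100 000). H2 is the two-dimensional Shannon
entropy of the cell shares. H2max is the entropy of the independence
table (exactly the maximum under the observed marginals); H2min comes
from the greedy largest-remainder pairing of marginals, capped at the
observed entropy — the observed web is itself a feasible allocation, so
the cap guarantees H2min ≤ H2 ≤ H2max, and the integer-allocation gap is
negligible at the ≥10⁴ totals the ×100 000 rule produces.
H2′ = (H2max − H2)/(H2max − H2min), defined as 0 with a warning when the
bounds coincide.

The shuffle-web null reassigns the observed nonzero cell values to
uniformly chosen distinct positions (dimensions and value multiset
preserved, marginals free). One consequence is worth stating plainly:
raw H2 depends only on the value multiset and is therefore *invariant*
under this null — its SES is undefined, and requesting it raises a
zero-spread error. The meaningful null statistic is H2′ (the default),
whose extremes move with the shuffled marginals. For sparse webs
dominated by hub genera — the structure real DOM–microbe webs show —
scattered nulls look nearly perfectly specialized (most values land in
their own row and column), so the observed web falls significantly
*below* the null: a negative SES, i.e. less specialized than expected by
chance, even though H2′ itself is well above the independence value.

## Synthetic data

The generator emulates a warming-microcosm design: 2 regions × 6
temperatures (5–30 °C) × 3 replicates = 36 samples. Element compositions
are drawn uniformly within C ∈ [4, 50], H/C ∈ [0.2, 2.3], O/C ∈ [0, 1.2],
N ≤ 3, S ≤ 2, P ≤ 1 with (H + N + P) forced even so DBE is integral, and
must populate ≥ 5 van Krevelen classes (relaxable for deliberately
narrow constraints). Intensities are log-normal (baseline ln-mean 13.8,
ln-sd 1.0, residual ln-sd 0.5) with multiplicative temperature trends of
±0.08 ln-units per °C for the planted responders (15% warm-accumulating
and 15% warm-depleting per region by default — strong, clearly
Spearman-detectable responses), optional latent-factor correlation
blocks, and occupancy thinning that pushes a configurable share (default
30%) of molecules below the 30% detection filter. Dark matter comes in
three couplings: `independent` (no shared structure — network
connectivity must drop when dark nodes replace known ones), `mirrored`
(each dark peak copies a distinct known molecule up to ln-sd 0.1 noise —
the dark pool is then statistically exchangeable with the known pool and
iDME must be near zero; sources are drawn without replacement precisely
so that no artificial dark–dark duplicate correlations are planted), and
`planted-links` (signed molecule–genus co-trends recoverable by the
correlation networks). Genus tables are compositional (closed to 1).

What the generator does *not* emulate: instrument-level structure (peak
shapes, isotopologues, mass-calibration drift), ionization suppression,
true chemical reaction constraints between formulas, and phylogenetic
structure among genera. Passing tests therefore demonstrate that the
estimators recover planted statistical structure under the stated noise
model, not that any particular field dataset will show these effects.

## Problem sizes and determinism

Default analysis scales (400-node networks, 100 replicates, 999 nulls and
repeats) follow the published protocol constants wired into `RunConfig`.
The test suite and the acceptance script run scaled-down versions chosen
to exercise every code path at comfortable runtimes: 250–500 molecules,
99 nulls/repeats, 200-node networks with 20 replicates, 10–20 seeds for
recovery rates. Every stochastic step takes an explicit seed; sub-seeds
are drawn from a master generator, and seeded runs are bit-identical
(asserted in the tests).

## Known limitations

* The exact-permutation Spearman null ignores ties (replicated
  temperatures); p-values for n < 10 are slightly conservative.
* H2min is a heuristic bound; it is exact for diagonal and independence
  webs and capped by the observed entropy in general, but the true
  integer-constrained minimum can be marginally lower.
* SparCC's sparsity assumption degrades when many components are strongly
  correlated; the exclusion loop mitigates but does not remove this.
* The TD dendrogram treats all transformations as unit steps; no attempt
  is made to weight chemically "larger" transformations differently.
* Per-sample iDME restricts pools to molecules present in the focal
  sample but inherits the global correlation matrix, per the protocol;
  sample-specific correlation re-estimation is out of scope.
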